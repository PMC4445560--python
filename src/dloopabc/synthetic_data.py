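"""Pseudo-observed data generation mirroring the study layout.

The default template reproduces the structure of the real dataset: 13
ancient spatiotemporal groups (193 sequences in total: 24 Near
Eastern/Anatolian, 169 European) plus modern country groups (100 Near
Eastern/Anatolian, 497 European), 240 bp sequences, ancient ages spanning
roughly 7,000-1,400 BCE.  Sequences are generated by the two-deme serial
coalescent at known parameters; the truth is written to a sidecar JSON so
the analysis pipeline never sees it through its regular inputs.

Sample ages are drawn uniformly within each group's period bounds; site
coordinates are drawn uniformly within a per-region bounding box.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import data_model as dm
from .coalescent_sim import (
    EU,
    NE,
    DemographicModel,
    MutationModel,
    SampleSpec,
    SamplingScheme,
    SimulatedSample,
    simulate_dataset,
)


@dataclass(frozen=True)
class GroupSpec:
    label: str                   # region_group label (metadata key)
    abc_group: str
    deme: str
    n: int
    age_bce_old: float           # older bound; 0 for modern
    age_bce_young: float
    lat_range: tuple[float, float]
    lon_range: tuple[float, float]

    @property
    def epoch(self) -> str:
        return "ancient" if self.age_bce_old > 0 else "modern"


_ANCIENT = [
    # label, abc_group, deme, n, old, young, lat box, lon box
    ("IR 7,000-5,000 BCE", "ancient_NE", NE, 10, 7000, 5000, (30, 37), (44, 54)),
    ("IR/S 4,000-1,400 BCE", "ancient_NE", NE, 6, 4000, 1400, (33, 37), (38, 48)),
    ("WA 6,400-5,700 BCE", "ancient_NE", NE, 8, 6400, 5700, (37, 40), (26, 30)),
    ("IT 6,000-5,500 BCE", "ancient_EU", EU, 5, 6000, 5500, (40, 42), (14, 18)),
    ("SECE 5,100-4,000 BCE", "ancient_EU", EU, 20, 5100, 4000, (46, 49), (16, 20)),
    ("SEE 6,200-5,500 BCE", "ancient_EU", EU, 34, 6200, 5500, (41, 45), (22, 28)),
    ("SEE 5,500-5,000 BCE", "ancient_EU", EU, 21, 5500, 5000, (41, 45), (22, 28)),
    ("SEE 5,000-4,000 BCE", "ancient_EU", EU, 8, 5000, 4000, (41, 45), (22, 28)),
    ("SEE 2,700-2,200 BCE", "ancient_EU", EU, 7, 2700, 2200, (41, 45), (22, 28)),
    ("SF 5,500-4,500 BCE", "ancient_EU", EU, 8, 5500, 4500, (43, 44.5), (3, 7)),
    ("SP 2,700-1,600 BCE", "ancient_EU", EU, 12, 2700, 1600, (37, 42), (-6, 0)),
    ("CWE 5,400-4,400 BCE", "ancient_EU", EU, 26, 5400, 4400, (47, 52), (2, 10)),
    ("CWE 4,400-2,500 BCE", "ancient_EU", EU, 28, 4400, 2500, (47, 52), (2, 10)),
]

_MODERN = [
    ("Turkey", "modern_NE", NE, 60, (37, 41), (27, 42)),
    ("Iran", "modern_NE", NE, 40, (28, 37), (45, 58)),
    ("Greece", "modern_EU", EU, 67, (37, 41), (20, 26)),
    ("Balkans", "modern_EU", EU, 70, (41, 45), (20, 27)),
    ("Italy", "modern_EU", EU, 80, (38, 45), (8, 17)),
    ("France", "modern_EU", EU, 80, (43, 49), (-1, 6)),
    ("Germany", "modern_EU", EU, 70, (48, 54), (7, 13)),
    ("Spain", "modern_EU", EU, 70, (37, 43), (-8, 1)),
    ("Britain", "modern_EU", EU, 60, (51, 55), (-4, 0)),
]

DEFAULT_GROUPS: tuple[GroupSpec, ...] = tuple(
    [GroupSpec(*row[:3], row[3], row[4], row[5], row[6], row[7]) for row in _ANCIENT]
    + [
        GroupSpec(label, abc, deme, n, 0.0, 0.0, latr, lonr)
        for label, abc, deme, n, latr, lonr in _MODERN
    ]
)


@dataclass(frozen=True)
class StudyTemplate:
    """Group layout of a pseudo-observed dataset (scalable)."""

    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    seq_length: int = 240
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")

    def scaled_groups(self) -> list[GroupSpec]:
        out = []
        for g in self.groups:
            n = max(2, round(g.n * self.scale))
            out.append(replace(g, n=n))
        return out

    @property
    def total_n(self) -> int:
        return sum(g.n for g in self.scaled_groups())


def _sanitize(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", label).strip("_")


def build_study(
    template: StudyTemplate, seed: int | np.random.Generator | None = None
) -> tuple[SamplingScheme, list[dm.SampleMetadata]]:
    """Draw ages and site coordinates and build the matching sampling scheme.

    Scheme entries are per-sample for ancient groups (each sample enters the
    genealogy at its own age) and per-group for modern ones (time 0).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    entries: list[SampleSpec] = []
    meta: list[dm.SampleMetadata] = []
    for g in template.scaled_groups():
        prefix = _sanitize(g.label)
        for i in range(g.n):
            sid = f"{prefix}_s{i:03d}"
            lat = float(rng.uniform(*g.lat_range))
            lon = float(rng.uniform(*g.lon_range))
            if g.epoch == "ancient":
                age = float(np.floor(rng.uniform(g.age_bce_young, g.age_bce_old)))
                t = dm.bce_to_generations(age)
            else:
                age, t = 0.0, 0.0
            entries.append(SampleSpec(deme=g.deme, time=t, n=1, group=g.label))
            meta.append(
                dm.SampleMetadata(
                    sample_id=sid,
                    site=f"{prefix}_site{i % 3}",
                    lat=lat,
                    lon=lon,
                    region_group=g.label,
                    age_bce_lo=age,
                    age_bce_hi=age,
                    epoch=g.epoch,
                    abc_group=g.abc_group,
                )
            )
    return SamplingScheme(entries), meta


def simulate_study(
    params: tuple[float, float, float, float],
    template: StudyTemplate | None = None,
    seed: int = 0,
    base_model: DemographicModel | None = None,
) -> tuple[SimulatedSample, list[dm.SampleMetadata]]:
    """Simulate a full pseudo-observed dataset at known parameters.

    The returned sample's group labels are region_group labels; use
    :func:`by_abc_group` for the four ABC sample groups.
    """
    template = template if template is not None else StudyTemplate()
    rng = np.random.default_rng(seed)
    scheme, meta = build_study(template, rng)
    mut = MutationModel(seq_length=template.seq_length)
    sample = simulate_dataset(params, scheme, mut, seed=rng, base_model=base_model)
    return sample, meta


def by_abc_group(
    sample: SimulatedSample, meta: Sequence[dm.SampleMetadata]
) -> dict[str, np.ndarray]:
    """Regroup a simulated sample's matrix into the four ABC sample groups."""
    abc_of = {m.region_group: m.abc_group for m in meta}
    out: dict[str, list[int]] = {}
    for i, g in enumerate(sample.groups):
        out.setdefault(abc_of[g], []).append(i)
    return {g: sample.matrix[idx] for g, idx in out.items()}


def generate_pseudo_observed(
    params: tuple[float, float, float, float],
    template: StudyTemplate | None = None,
    seed: int = 0,
    outdir: str | Path = ".",
    base_model: DemographicModel | None = None,
) -> dict[str, Path]:
    """Write a pseudo-observed dataset (FASTA + metadata TSV + truth JSON)."""
    template = template if template is not None else StudyTemplate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample, meta = simulate_study(params, template, seed, base_model)
    ids = [m.sample_id for m in meta]
    aln = sample.to_alignment(ids=ids)
    fasta = outdir / "sequences.fasta"
    tsv = outdir / "metadata.tsv"
    sidecar = outdir / "truth.json"
    dm.write_fasta(aln.records, fasta)
    dm.write_metadata(meta, tsv)
    sidecar.write_text(
        json.dumps(
            {
                "params": {
                    "N_D": params[0],
                    "P": params[1],
                    "M_E": params[2],
                    "M_L": params[3],
                },
                "seed": seed,
                "scale": template.scale,
                "seq_length": template.seq_length,
                "n_sequences": len(ids),
            },
            indent=2,
        )
    )
    return {"fasta": fasta, "metadata": tsv, "truth": sidecar}


def make_toy_fixtures() -> dict[str, dm.AlignedSequences]:
    """Deterministic miniature alignments used in examples and tests.

    ``sf_monomorphic``: eight identical 240 bp sequences (a Southern-France
    style fixed group); ``tajima_toy``: the four-sequence {AA, AT, TT, TT}
    alignment; ``fst_fixed_a``/``fst_fixed_b``: two groups fixed for
    haplotypes one difference apart.
    """
    base240 = ("ACGT" * 60)[:240]
    sf = dm.AlignedSequences(
        [
            dm.SequenceRecord(id=f"SF_{i}", seq=base240, anchor_start=16_023)
            for i in range(8)
        ],
        window=dm.ABC_WINDOW,
    )
    tajima = dm.AlignedSequences(
        [
            dm.SequenceRecord(id=f"t{i}", seq=s, anchor_start=1)
            for i, s in enumerate(["AA", "AT", "TT", "TT"])
        ],
        window=(1, 2),
    )
    seq_a = "A" * 10
    seq_b = "A" * 9 + "T"
    fst_a = dm.AlignedSequences(
        [dm.SequenceRecord(id=f"a{i}", seq=seq_a, anchor_start=1) for i in range(2)],
        window=(1, 10),
    )
    fst_b = dm.AlignedSequences(
        [dm.SequenceRecord(id=f"b{i}", seq=seq_b, anchor_start=1) for i in range(2)],
        window=(1, 10),
    )
    return {
        "sf_monomorphic": sf,
        "tajima_toy": tajima,
        "fst_fixed_a": fst_a,
        "fst_fixed_b": fst_b,
    }
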