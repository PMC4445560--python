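"""Input handling for aligned cattle mtDNA control-region (D-loop) data.

Sequences are short HVR1 fragments anchored to the *Bos taurus* mitochondrial
reference V00654 (1-based, inclusive coordinates).  Three windows are used in
practice: the full 434 bp amplicon (15,914-16,347), the 399 bp fragment shared
by all ancient sequences (15,914-16,312), and the 240 bp window common to the
modern data (16,023-16,262).

Calendar ages (years BCE) are converted to generations before present with a
6-year generation interval and the present fixed at 2000 CE, so that
8,500 BCE = 1,750 generations BP and 6,400 BCE = 1,400 generations BP.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("dloopabc")

# -- reference coordinates (1-based inclusive on V00654) and time constants --

REFERENCE_ACCESSION = "V00654"
FRAGMENT_WINDOW = (15_914, 16_347)   # 434 bp amplicon
STATS_WINDOW = (15_914, 16_312)      # 399 bp descriptive-statistics window
ABC_WINDOW = (16_023, 16_262)        # 240 bp window shared with modern data

GENERATION_TIME_YEARS = 6.0
PRESENT_YEAR_CE = 2000.0

VALID_CHARS = frozenset("ACGTN-?")
_AMBIGUITY_CODES = frozenset("RYSWKMBDHV")

ABC_GROUPS = ("ancient_NE", "ancient_EU", "modern_NE", "modern_EU")

# region_group -> abc_group for the 13 ancient spatiotemporal groups plus the
# modern country groups emitted by the synthetic generator.  Users with their
# own groupings supply a mapping file instead (JSON or key=value).
DEFAULT_GROUP_MAP: dict[str, str] = {
    # ancient Near East / Anatolia (n = 24)
    "IR 7,000-5,000 BCE": "ancient_NE",
    "IR/S 4,000-1,400 BCE": "ancient_NE",
    "WA 6,400-5,700 BCE": "ancient_NE",
    # ancient Europe (n = 169)
    "IT 6,000-5,500 BCE": "ancient_EU",
    "SECE 5,100-4,000 BCE": "ancient_EU",
    "SEE 6,200-5,500 BCE": "ancient_EU",
    "SEE 5,500-5,000 BCE": "ancient_EU",
    "SEE 5,000-4,000 BCE": "ancient_EU",
    "SEE 2,700-2,200 BCE": "ancient_EU",
    "SF 5,500-4,500 BCE": "ancient_EU",
    "SP 2,700-1,600 BCE": "ancient_EU",
    "CWE 5,400-4,400 BCE": "ancient_EU",
    "CWE 4,400-2,500 BCE": "ancient_EU",
    # modern country groups
    "Turkey": "modern_NE",
    "Iran": "modern_NE",
    "Greece": "modern_EU",
    "Balkans": "modern_EU",
    "Italy": "modern_EU",
    "France": "modern_EU",
    "Germany": "modern_EU",
    "Spain": "modern_EU",
    "Britain": "modern_EU",
}

METADATA_COLUMNS = (
    "sample_id",
    "site",
    "lat",
    "lon",
    "region_group",
    "age_bce_lo",
    "age_bce_hi",
    "epoch",
)


class ValidationError(ValueError):
    """Raised when an input file violates the documented schema."""


# ---------------------------------------------------------------------------
# sequence records
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A single aligned haploid sequence anchored on the reference.

    ``anchor_start`` is the 1-based reference position of the first base of
    ``seq``; gaps relative to the reference are not modelled (inputs are
    pre-aligned fragments of fixed coordinates).
    """

    id: str
    seq: str
    anchor_start: int = FRAGMENT_WINDOW[0]

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        if self.anchor_start < 1:
            raise ValidationError(f"record {self.id!r}: anchor_start must be >= 1")
        bad = set(self.seq) - VALID_CHARS
        if bad:
            raise ValidationError(
                f"record {self.id!r}: invalid characters {sorted(bad)}"
            )

    @property
    def anchor_end(self) -> int:
        return self.anchor_start + len(self.seq) - 1


def read_fasta(path: str | Path, anchor_start: int = FRAGMENT_WINDOW[0]) -> list[SequenceRecord]:
    """Read aligned sequences from FASTA.

    Sequences are uppercased; IUPAC ambiguity codes other than N are mapped
    to N with a warning.  Duplicate ids and non-FASTA content are errors.
    """
    path = Path(path)
    _check_fasta_syntax(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        ambig = set(seq) & _AMBIGUITY_CODES
        if ambig:
            logger.warning(
                "%s: record %s: ambiguity codes %s mapped to N",
                path, rec.id, "".join(sorted(ambig)),
            )
            seq = "".join("N" if c in _AMBIGUITY_CODES else c for c in seq)
        records.append(SequenceRecord(id=rec.id, seq=seq, anchor_start=anchor_start))
    return records


def _check_fasta_syntax(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValidationError(
                    f"{path}: line {lineno}: expected FASTA header, got {stripped[:30]!r}"
                )
            return
    raise ValidationError(f"{path}: empty FASTA file")


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# windowed alignments
# ---------------------------------------------------------------------------

_ENCODE = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
_DECODE = np.array(list("ACGT"))


@dataclass
class AlignedSequences:
    """A rectangular alignment windowed to a common reference interval."""

    records: list[SequenceRecord]
    window: tuple[int, int]

    def __post_init__(self) -> None:
        start, end = self.window
        expected = end - start + 1
        if expected < 1:
            raise ValidationError(f"invalid window {self.window}")
        for r in self.records:
            if len(r.seq) != expected:
                raise ValidationError(
                    f"record {r.id!r}: length {len(r.seq)} != window length {expected}"
                )

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return self.window[1] - self.window[0] + 1

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def to_matrix(self) -> np.ndarray:
        """Encode as int8 matrix: A,C,G,T -> 0..3; N, -, ? -> -1 (missing)."""
        if not self.records:
            return np.empty((0, self.length), dtype=np.int8)
        flat = np.frombuffer(
            "".join(r.seq for r in self.records).encode("ascii"), dtype=np.uint8
        )
        return _ENCODE[flat].reshape(self.n, self.length)

    def subset(self, indices: Sequence[int]) -> "AlignedSequences":
        return AlignedSequences([self.records[i] for i in indices], self.window)


def matrix_to_alignment(
    matrix: np.ndarray,
    ids: Sequence[str] | None = None,
    window: tuple[int, int] = ABC_WINDOW,
) -> AlignedSequences:
    """Build an AlignedSequences from an integer-encoded matrix (0..3, -1=N)."""
    n, length = matrix.shape
    if ids is None:
        ids = [f"s{i}" for i in range(n)]
    chars = np.where(matrix >= 0, _DECODE[np.clip(matrix, 0, 3)], "N")
    records = [
        SequenceRecord(id=str(ids[i]), seq="".join(chars[i]), anchor_start=window[0])
        for i in range(n)
    ]
    return AlignedSequences(records, window)


def extract_window(
    records: Sequence[SequenceRecord], start: int, end: int
) -> AlignedSequences:
    """Cut every record to reference interval [start, end] (1-based inclusive)."""
    if end < start:
        raise ValidationError(f"invalid window ({start}, {end})")
    not_covering = [
        r.id for r in records if r.anchor_start > start or r.anchor_end < end
    ]
    if not_covering:
        raise ValidationError(
            f"records not covering window ({start}, {end}): {not_covering}"
        )
    out = []
    for r in records:
        offset = start - r.anchor_start
        out.append(
            SequenceRecord(
                id=r.id,
                seq=r.seq[offset : offset + (end - start + 1)],
                anchor_start=start,
            )
        )
    return AlignedSequences(out, (start, end))


# ---------------------------------------------------------------------------
# time conversion
# ---------------------------------------------------------------------------

def bce_to_generations(
    age_bce: float,
    generation_time: float = GENERATION_TIME_YEARS,
    present_ce: float = PRESENT_YEAR_CE,
) -> float:
    """Convert years BCE to generations before present.

    Negative BCE values (CE dates) are allowed.  With the defaults,
    8,500 BCE -> 1,750 generations and 6,400 BCE -> 1,400 generations.
    """
    if generation_time <= 0:
        raise ValueError("generation_time must be positive")
    return (age_bce + present_ce) / generation_time


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleMetadata:
    sample_id: str
    site: str
    lat: float
    lon: float
    region_group: str
    age_bce_lo: float   # older bound (larger BCE value)
    age_bce_hi: float   # younger bound
    epoch: str          # "ancient" | "modern"
    abc_group: str = ""

    def __post_init__(self) -> None:
        if self.epoch not in ("ancient", "modern"):
            raise ValidationError(
                f"sample {self.sample_id!r}: epoch must be ancient|modern"
            )
        if self.age_bce_lo < self.age_bce_hi:
            raise ValidationError(
                f"sample {self.sample_id!r}: age_bce_lo ({self.age_bce_lo}) must be"
                f" the older bound (>= age_bce_hi {self.age_bce_hi})"
            )
        if not (-90 <= self.lat <= 90) or not (-180 <= self.lon <= 180):
            raise ValidationError(f"sample {self.sample_id!r}: invalid coordinates")

    @property
    def age_bce_mid(self) -> float:
        return 0.5 * (self.age_bce_lo + self.age_bce_hi)


def load_group_map(path: str | Path) -> dict[str, str]:
    """Read a region_group -> abc_group mapping from JSON or key=value text."""
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        mapping = json.loads(text)
    else:
        mapping = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValidationError(f"{path}: line {lineno}: expected key=value")
            key, value = line.split("=", 1)
            mapping[key.strip()] = value.strip()
    bad = {g for g in mapping.values()} - set(ABC_GROUPS)
    if bad:
        raise ValidationError(f"{path}: unknown abc_group labels {sorted(bad)}")
    return mapping


def read_metadata(
    path: str | Path, group_map: Mapping[str, str] | None = None
) -> list[SampleMetadata]:
    """Read and validate the sample-metadata TSV.

    ``abc_group`` is derived from region_group via ``group_map`` (default:
    the study's 13 ancient groups plus the bundled modern country groups).
    """
    group_map = dict(group_map) if group_map is not None else DEFAULT_GROUP_MAP
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site": str})
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{path}: duplicate sample ids {dups}")
    if df[["lat", "lon"]].isna().any().any():
        bad = df.loc[df[["lat", "lon"]].isna().any(axis=1), "sample_id"].tolist()
        raise ValidationError(f"{path}: missing coordinates for {bad}")
    rows: list[SampleMetadata] = []
    for rec in df.itertuples(index=False):
        if rec.region_group not in group_map:
            raise ValidationError(
                f"{path}: sample {rec.sample_id!r}: unknown region_group"
                f" {rec.region_group!r} (not in group map)"
            )
        rows.append(
            SampleMetadata(
                sample_id=rec.sample_id,
                site=rec.site,
                lat=float(rec.lat),
                lon=float(rec.lon),
                region_group=rec.region_group,
                age_bce_lo=float(rec.age_bce_lo),
                age_bce_hi=float(rec.age_bce_hi),
                epoch=rec.epoch,
                abc_group=group_map[rec.region_group],
            )
        )
    return rows


def write_metadata(rows: Iterable[SampleMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "site": m.site,
                "lat": m.lat,
                "lon": m.lon,
                "region_group": m.region_group,
                "age_bce_lo": m.age_bce_lo,
                "age_bce_hi": m.age_bce_hi,
                "epoch": m.epoch,
            }
            for m in rows
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def sample_ages_bce(
    rows: Sequence[SampleMetadata], policy: str = "sample_midpoint"
) -> dict[str, float]:
    """Point age per sample for the serial coalescent.

    ``sample_midpoint`` (default): midpoint of each sample's own age range.
    ``group_midpoint``: midpoint of the pooled range of the sample's
    region_group, so all members of a group enter the genealogy together.
    """
    if policy == "sample_midpoint":
        return {m.sample_id: m.age_bce_mid for m in rows}
    if policy == "group_midpoint":
        lo: dict[str, float] = {}
        hi: dict[str, float] = {}
        for m in rows:
            lo[m.region_group] = max(lo.get(m.region_group, -np.inf), m.age_bce_lo)
            hi[m.region_group] = min(hi.get(m.region_group, np.inf), m.age_bce_hi)
        return {
            m.sample_id: 0.5 * (lo[m.region_group] + hi[m.region_group]) for m in rows
        }
    raise ValueError(f"unknown age policy {policy!r}")


def group_alignments(
    aln: AlignedSequences,
    rows: Sequence[SampleMetadata],
    by: str = "abc_group",
) -> dict[str, AlignedSequences]:
    """Partition an alignment by a metadata field (abc_group or region_group)."""
    meta = {m.sample_id: m for m in rows}
    missing = [r.id for r in aln.records if r.id not in meta]
    if missing:
        raise ValidationError(f"sequences without metadata rows: {missing}")
    out: dict[str, list[int]] = {}
    for i, rec in enumerate(aln.records):
        out.setdefault(getattr(meta[rec.id], by), []).append(i)
    return {g: aln.subset(idx) for g, idx in out.items()}
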