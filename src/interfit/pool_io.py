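"""Data model and IO for insertion pools, barcode count tables and community compositions.

The pipeline consumes BarSeq-style "poolcount" tables: one row per barcoded
transposon insertion strain (genomic location, gene assignment, fractional
position within the gene) followed by one integer read-count column per
sequencing sample.  Sample metadata (which condition, which biological
replicate, T0 vs endpoint) lives in a separate tab-separated table.

Community compositions are encoded as presence/absence bit triples over the
three partner species of the focal *E. coli* strain — *Geotrichum candidum*
(Gc), *Hafnia alvei* (Ha) and *Penicillium camemberti* (Pc) — in that fixed
bit order, so growth alone is ``000`` and the full four-species community is
``111``.  Community complexity level is one plus the number of partners
present (the focal species is always there).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

PARTNERS: tuple[str, str, str] = ("Gc", "Ha", "Pc")

POOLCOUNT_COLUMNS = ("barcode", "rcbarcode", "scaffold", "strand", "pos", "locusId", "f")


class PoolFormatError(ValueError):
    """Raised when a poolcount or metadata file violates the expected dialect."""


@dataclass(frozen=True, order=True)
class ConditionCode:
    """Presence/absence of the three partner species, bit order (Gc, Ha, Pc)."""

    bits: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.bits) != 3 or any(b not in (0, 1) for b in self.bits):
            raise ValueError(f"bits must be a (0|1) triple, got {self.bits!r}")

    @classmethod
    def from_partners(cls, partner_set: Iterable[str]) -> "ConditionCode":
        partners = set(partner_set)
        unknown = partners - set(PARTNERS)
        if unknown:
            raise ValueError(f"unknown partner name(s): {sorted(unknown)}")
        return cls(tuple(int(p in partners) for p in PARTNERS))

    @classmethod
    def from_string(cls, s: str) -> "ConditionCode":
        """Parse either a bitstring ('011') or a partner-name label ('HaPc', 'ALONE')."""
        s = s.strip()
        if set(s) <= {"0", "1"} and len(s) == 3:
            return cls(tuple(int(c) for c in s))
        if s.upper() == "ALONE":
            return cls((0, 0, 0))
        rest, partners = s, []
        for p in sorted(PARTNERS, key=len, reverse=True):
            if p in rest:
                partners.append(p)
                rest = rest.replace(p, "", 1)
        if rest:
            raise ValueError(f"cannot parse condition label {s!r}")
        return cls.from_partners(partners)

    @property
    def partners(self) -> frozenset[str]:
        return frozenset(p for p, b in zip(PARTNERS, self.bits) if b)

    @property
    def level(self) -> int:
        """Community complexity level: focal species plus number of partners."""
        return 1 + sum(self.bits)

    @property
    def code(self) -> str:
        return "".join(str(b) for b in self.bits)

    @property
    def label(self) -> str:
        if self.level == 1:
            return "ALONE"
        return "".join(p for p in PARTNERS if p in self.partners)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.label


ALONE = ConditionCode((0, 0, 0))

#: The 8 compositions in deterministic order: by complexity level, then bitstring.
ALL_CONDITIONS: tuple[ConditionCode, ...] = tuple(
    sorted(
        (ConditionCode((a, b, c)) for a in (0, 1) for b in (0, 1) for c in (0, 1)),
        key=lambda c: (c.level, c.code),
    )
)

INTERACTIVE_CONDITIONS: tuple[ConditionCode, ...] = tuple(
    c for c in ALL_CONDITIONS if c.level >= 2
)


def encode_condition(partner_set: Iterable[str]) -> ConditionCode:
    """Encode a set of partner names as a presence/absence code, e.g. {Ha, Pc} -> 011."""
    return ConditionCode.from_partners(partner_set)


def decode_condition(code: ConditionCode | str) -> frozenset[str]:
    """Inverse of :func:`encode_condition`."""
    if isinstance(code, str):
        code = ConditionCode.from_string(code)
    return code.partners


@dataclass(frozen=True)
class InsertionStrain:
    """One barcoded transposon mutant in the pooled library.

    ``locus_id`` is ``None`` for intergenic insertions; ``gene_fraction`` is
    the fractional position of the insertion within the gene body (5'->3'),
    defined only when the strain is gene-assigned.
    """

    barcode: str
    scaffold: str
    position: int
    strand: str
    locus_id: str | None = None
    gene_fraction: float | None = None
    rcbarcode: str = ""

    def __post_init__(self) -> None:
        if (self.locus_id is None) != (self.gene_fraction is None):
            raise ValueError(
                f"strain {self.barcode}: gene_fraction must be set iff locus_id is set"
            )
        if self.gene_fraction is not None and not (0.0 <= self.gene_fraction <= 1.0):
            raise ValueError(
                f"strain {self.barcode}: gene_fraction {self.gene_fraction} outside [0, 1]"
            )

    @property
    def is_intergenic(self) -> bool:
        return self.locus_id is None


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing sample: its condition, biological replicate and role."""

    sample_id: str
    condition: ConditionCode
    replicate: int
    role: str  # "T0" or "endpoint"

    def __post_init__(self) -> None:
        if self.role not in ("T0", "endpoint"):
            raise ValueError(f"sample {self.sample_id}: role must be T0 or endpoint")
        if self.replicate < 1:
            raise ValueError(f"sample {self.sample_id}: replicate must be >= 1")


def validate_samples(samples: Sequence[SampleMeta]) -> None:
    seen: set[tuple] = set()
    for s in samples:
        key = (s.condition, s.replicate, s.role)
        if key in seen:
            raise PoolFormatError(
                f"duplicate (condition, replicate, role) combination: {key}"
            )
        seen.add(key)
    if any(s.role == "endpoint" for s in samples) and not any(
        s.role == "T0" for s in samples
    ):
        raise PoolFormatError("endpoint samples present but no T0 sample in metadata")


# ---------------------------------------------------------------------------
# poolcount IO


def read_poolcount(path: str | Path) -> tuple[list[InsertionStrain], pd.DataFrame]:
    """Read a poolcount TSV into a strain list and a barcode x sample count matrix.

    The dialect is a header row with the seven fixed leading columns
    ``barcode rcbarcode scaffold strand pos locusId f`` followed by one
    integer column per sample.  Empty ``locusId``/``f`` cells mark intergenic
    strains.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    header = tuple(df.columns[: len(POOLCOUNT_COLUMNS)])
    if header != POOLCOUNT_COLUMNS:
        missing = [c for c in POOLCOUNT_COLUMNS if c not in df.columns[:7]]
        raise PoolFormatError(
            f"{path}: malformed poolcount header; expected leading columns "
            f"{list(POOLCOUNT_COLUMNS)}, got {list(header)}"
            + (f" (missing {missing})" if missing else "")
        )
    sample_ids = list(df.columns[len(POOLCOUNT_COLUMNS) :])

    pool: list[InsertionStrain] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        locus = row.locusId or None
        frac_raw = row.f
        frac = float(frac_raw) if (locus is not None and frac_raw != "") else None
        if locus is not None and frac is None:
            raise PoolFormatError(
                f"{path}:{i}: gene-assigned strain {row.barcode} has empty f column"
            )
        pool.append(
            InsertionStrain(
                barcode=row.barcode,
                rcbarcode=row.rcbarcode,
                scaffold=row.scaffold,
                position=int(row.pos),
                strand=row.strand,
                locus_id=locus,
                gene_fraction=frac,
            )
        )

    counts = pd.DataFrame(index=[s.barcode for s in pool], columns=sample_ids)
    for col in sample_ids:
        raw = df[col]
        try:
            vals = raw.astype(int)
        except ValueError as exc:
            bad = raw[~raw.str.fullmatch(r"-?\d+")]
            rowno = bad.index[0] + 2 if len(bad) else "?"
            raise ValueError(
                f"{path}: non-integer count in column {col!r} at row {rowno}"
            ) from exc
        if (vals < 0).any():
            rowno = int(vals[vals < 0].index[0]) + 2
            raise ValueError(f"{path}: negative count in column {col!r} at row {rowno}")
        counts[col] = vals.to_numpy()
    counts.index.name = "barcode"
    return pool, counts.astype(int)


def write_poolcount(
    pool: Sequence[InsertionStrain], counts: pd.DataFrame, path: str | Path
) -> None:
    """Write the dialect :func:`read_poolcount` accepts; samples sorted by id."""
    barcodes = [s.barcode for s in pool]
    if set(barcodes) != set(counts.index) or len(barcodes) != len(counts.index):
        raise ValueError("pool barcodes and count-matrix rows are inconsistent")
    sample_ids = sorted(counts.columns)
    out = pd.DataFrame(
        {
            "barcode": barcodes,
            "rcbarcode": [s.rcbarcode for s in pool],
            "scaffold": [s.scaffold for s in pool],
            "strand": [s.strand for s in pool],
            "pos": [s.position for s in pool],
            "locusId": [s.locus_id or "" for s in pool],
            "f": ["" if s.gene_fraction is None else format(s.gene_fraction, "g") for s in pool],
        }
    )
    for col in sample_ids:
        out[col] = counts.loc[barcodes, col].to_numpy()
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# sample metadata IO


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata TSV with columns sample_id, condition, replicate, role."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "condition", "replicate", "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PoolFormatError(f"{path}: metadata missing column(s) {missing}")
    samples = [
        SampleMeta(
            sample_id=r.sample_id,
            condition=ConditionCode.from_string(r.condition),
            replicate=int(r.replicate),
            role=r.role,
        )
        for r in df.itertuples(index=False)
    ]
    validate_samples(samples)
    return samples


def write_sample_meta(samples: Sequence[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "condition": [s.condition.label for s in samples],
            "replicate": [s.replicate for s in samples],
            "role": [s.role for s in samples],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
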