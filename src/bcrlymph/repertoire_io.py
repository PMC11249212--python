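"""Reading, filtering and collapsing clonotype tables.

Input tables follow the AIRR Rearrangement dialect (tab-separated, header
row, ``v_identity`` as a fraction in [0, 1]). A clonotype is a unique CDR3
nucleotide sequence; record-level filters discard non-productive
rearrangements and sequences seen fewer than twice. Somatic hypermutation
is called from V-segment germline identity at the 98% threshold
(inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    EmptyRepertoireError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Required columns of an input clonotype table.
AIRR_COLUMNS = (
    "sequence_id",
    "productive",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_aa",
    "duplicate_count",
    "v_identity",
)

#: Germline-identity threshold (percent) at or below which a clonotype is
#: called somatically hypermutated.
SHM_IDENTITY_THRESHOLD_PCT = 98.0

_TRUE = {"t", "true", "1", "yes"}
_FALSE = {"f", "false", "0", "no"}

#: Column layout of :attr:`Repertoire.clonotypes`.
CLONOTYPE_COLUMNS = (
    "cdr3_nt",
    "cdr3_aa",
    "v_gene",
    "d_gene",
    "j_gene",
    "read_count",
    "fraction",
    "v_identity_pct",
    "is_hypermutated",
)


@dataclass
class ClonotypeRecord:
    """One VDJ rearrangement row from a clonotype table."""

    sequence_id: str
    cdr3_nt: str
    cdr3_aa: str
    v_call: str
    d_call: str
    j_call: str
    read_count: int
    productive: bool
    v_identity_pct: float

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValidationError(
                f"read_count must be >= 0, got {self.read_count}"
            )
        if not 0.0 <= self.v_identity_pct <= 100.0:
            raise ValidationError(
                f"v_identity_pct must lie in [0, 100], got {self.v_identity_pct}"
            )


@dataclass
class Repertoire:
    """One sample's filtered, fraction-normalized clonotype list.

    ``clonotypes`` is a DataFrame with columns :data:`CLONOTYPE_COLUMNS`,
    sorted by ``fraction`` descending (ties: ``read_count`` descending,
    then ``cdr3_nt`` lexicographic). Fractions sum to 1.
    """

    sample_id: str
    label: str
    clonotypes: pd.DataFrame
    total_reads: int
    tissue: str = ""
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.clonotypes) == 0:
            raise EmptyRepertoireError(
                f"repertoire {self.sample_id!r} has no clonotypes"
            )
        frac = self.clonotypes["fraction"].to_numpy()
        if abs(frac.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"clonotype fractions of {self.sample_id!r} sum to "
                f"{frac.sum():.12f}, not 1"
            )
        if np.any(np.diff(frac) > 1e-12):
            raise ValidationError("clonotypes must be sorted by fraction")
        if self.clonotypes["cdr3_nt"].duplicated().any():
            raise ValidationError("clonotype cdr3_nt keys must be unique")
        if self.total_reads <= 0:
            raise ValidationError("total_reads must be positive")

    @property
    def richness(self) -> int:
        return len(self.clonotypes)

    @property
    def fractions(self) -> np.ndarray:
        return self.clonotypes["fraction"].to_numpy()


def call_shm(v_identity_pct: float) -> bool:
    """Somatic-hypermutation call from V germline identity (percent).

    Returns ``True`` iff identity <= 98.0 (boundary inclusive): a V
    segment that diverged by at least 2% from its germline reference is
    considered hypermutated.
    """
    if not 0.0 <= v_identity_pct <= 100.0:
        raise ValidationError(
            f"v_identity_pct must lie in [0, 100], got {v_identity_pct}"
        )
    return v_identity_pct <= SHM_IDENTITY_THRESHOLD_PCT


def _parse_bool(raw: str) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"unparseable boolean {raw!r}")


def read_airr_table(path: str | Path) -> list[ClonotypeRecord]:
    """Read an AIRR Rearrangement TSV into clonotype records.

    ``v_identity`` is stored on disk as a fraction in [0, 1] per the AIRR
    standard and converted to percent internally. Malformed rows are
    skipped with a logged warning naming the row numbers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    missing = [c for c in AIRR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path} is missing required column(s): {', '.join(missing)}"
        )
    if len(df) == 0:
        raise EmptyInputError(f"{path} contains a header but no records")

    records: list[ClonotypeRecord] = []
    bad_rows: list[int] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            records.append(
                ClonotypeRecord(
                    sequence_id=str(row.sequence_id),
                    cdr3_nt="" if pd.isna(row.junction) else str(row.junction),
                    cdr3_aa="" if pd.isna(row.junction_aa) else str(row.junction_aa),
                    v_call=str(row.v_call),
                    d_call=str(row.d_call),
                    j_call=str(row.j_call),
                    read_count=int(row.duplicate_count),
                    productive=_parse_bool(row.productive),
                    v_identity_pct=float(row.v_identity) * 100.0,
                )
            )
        except (ValueError, TypeError, ValidationError):
            bad_rows.append(i)
    if bad_rows:
        logger.warning(
            "%s: skipped %d malformed row(s) at line(s) %s",
            path, len(bad_rows), bad_rows,
        )
    return records


def filter_records(records: list[ClonotypeRecord]) -> list[ClonotypeRecord]:
    """Record-level filter: keep productive records with >= 2 reads.

    Idempotent; preserves order. Discard counts are logged by reason.
    """
    kept = []
    n_nonproductive = 0
    n_low_count = 0
    for rec in records:
        if not rec.productive:
            n_nonproductive += 1
        elif rec.read_count < 2:
            n_low_count += 1
        else:
            kept.append(rec)
    if n_nonproductive or n_low_count:
        logger.info(
            "discarded %d non-productive and %d low-count (<2 reads) records",
            n_nonproductive, n_low_count,
        )
    return kept


def strip_allele(call: str) -> str:
    """Drop the allele suffix (``IGHV4-34*01`` -> ``IGHV4-34``).

    Only the ``*`` suffix is removed; orphon names like ``IGHV4/OR15-8``
    pass through verbatim. Ambiguous comma-separated multi-gene calls
    resolve to the first listed gene.
    """
    call = call.strip()
    if "," in call:
        first = call.split(",", 1)[0].strip()
        logger.debug("ambiguous gene call %r resolved to %r", call, first)
        call = first
    return call.split("*", 1)[0]


def collapse_to_repertoire(
    records: list[ClonotypeRecord],
    sample_id: str,
    label: str = "unknown",
    tissue: str = "",
) -> Repertoire:
    """Collapse filtered records into a clonotype-level repertoire.

    Records are grouped by CDR3 nucleotide sequence (the clonotype key);
    read counts are summed within a group, the representative V/D/J calls
    and amino-acid sequence come from the highest-count member, and the
    group germline identity is the read-count-weighted mean. Fractions
    are group counts over the retained total. The result is sorted by
    fraction descending with deterministic tie-breaking.
    """
    if not records:
        raise EmptyRepertoireError(
            f"no records remain for sample {sample_id!r}; a repertoire "
            "must contain at least one clonotype"
        )
    groups: dict[str, list[ClonotypeRecord]] = {}
    for rec in records:
        if not rec.cdr3_nt:
            raise ValidationError(
                f"record {rec.sequence_id!r} has an empty CDR3 nucleotide "
                "sequence; retained records must have one"
            )
        groups.setdefault(rec.cdr3_nt, []).append(rec)

    rows = []
    for cdr3_nt, members in groups.items():
        counts = np.array([m.read_count for m in members])
        total = int(counts.sum())
        rep = members[int(np.argmax(counts))]
        ident = float(np.average(
            [m.v_identity_pct for m in members], weights=counts,
        ))
        rows.append({
            "cdr3_nt": cdr3_nt,
            "cdr3_aa": rep.cdr3_aa,
            "v_gene": strip_allele(rep.v_call),
            "d_gene": strip_allele(rep.d_call),
            "j_gene": strip_allele(rep.j_call),
            "read_count": total,
            "v_identity_pct": ident,
            "is_hypermutated": call_shm(ident),
        })
    df = pd.DataFrame(rows)
    grand_total = int(df["read_count"].sum())
    df["fraction"] = df["read_count"] / grand_total
    df = df.sort_values(
        ["fraction", "read_count", "cdr3_nt"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df = df[list(CLONOTYPE_COLUMNS)]
    return Repertoire(
        sample_id=sample_id,
        label=label,
        tissue=tissue,
        clonotypes=df,
        total_reads=grand_total,
    )


def write_airr_table(repertoire: Repertoire, path: str | Path) -> None:
    """Write a repertoire back out as an AIRR Rearrangement TSV."""
    df = repertoire.clonotypes
    out = pd.DataFrame({
        "sequence_id": [
            f"{repertoire.sample_id}-{i + 1}" for i in range(len(df))
        ],
        "productive": "T",
        "v_call": df["v_gene"].to_numpy(),
        "d_call": df["d_gene"].to_numpy(),
        "j_call": df["j_gene"].to_numpy(),
        "junction": df["cdr3_nt"].to_numpy(),
        "junction_aa": df["cdr3_aa"].to_numpy(),
        "duplicate_count": df["read_count"].to_numpy(),
        "v_identity": np.round(df["v_identity_pct"].to_numpy() / 100.0, 6),
    })
    out.to_csv(path, sep="\t", index=False)


def load_repertoire(
    path: str | Path,
    sample_id: str,
    label: str = "unknown",
    tissue: str = "",
) -> Repertoire:
    """Read, filter and collapse one clonotype table."""
    records = filter_records(read_airr_table(path))
    return collapse_to_repertoire(records, sample_id, label, tissue)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest TSV (sample_id, label, path[, tissue, seed])."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, comment="#")
    required = {"sample_id", "label", "path"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(
            f"manifest {path} is missing column(s): {', '.join(sorted(missing))}"
        )
    return df


def load_cohort(manifest_path: str | Path) -> list[Repertoire]:
    """Load every sample listed in a manifest, relative to its location."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    reps = []
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        tissue = getattr(row, "tissue", "") or ""
        reps.append(load_repertoire(p, row.sample_id, row.label, tissue))
    return reps
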