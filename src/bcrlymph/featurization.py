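"""Fixed-length top-n clonotype feature vectors.

Each repertoire is summarized by its ``n`` most dominant clonotypes.
Every clonotype slot contributes 12 numeric features — the clonotype
fraction, the CDR3 amino-acid length and the ten mean Kidera factors —
plus one-hot encodings of its V, D and J genes over vocabularies learned
from the training repertoires. Repertoires with fewer than ``n``
clonotypes are zero-padded; genes unseen in training encode as an
all-zero block. Four repertoire-level metrics (clonality, Shannon index,
richness, SHM clonotype fraction) are appended, giving a total width of
``n * (12 + |V| + |D| + |J|) + 4``.

Optional standardization (zero mean, unit variance, fitted on training
vectors only) applies to the numeric columns; one-hot columns are left
untouched. Padding slots are exactly zero in the unscaled representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .kidera import kidera_descriptor
from .repertoire_io import Repertoire
from .repertoire_metrics import compute_metrics

#: Numeric features per clonotype slot: fraction, CDR3 length, KF1..KF10.
NUMERIC_PER_SLOT = 12

#: Repertoire-level block appended after the clonotype slots.
REPERTOIRE_BLOCK = ("clonality", "shannon", "richness", "shm_fraction")

#: Admissible values of n (the top-clonotype cut).
ALLOWED_N = frozenset(range(1, 11)) | {20, 50, 100}


@dataclass
class FeatureSchema:
    """Layout (and optional scaling parameters) of the feature vector."""

    n_clonotypes: int
    v_vocab: list[str]
    d_vocab: list[str]
    j_vocab: list[str]
    scaling_enabled: bool = False
    scaling_mean: np.ndarray | None = None
    scaling_sd: np.ndarray | None = None
    feature_names: list[str] = field(init=False)
    numeric_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.n_clonotypes not in ALLOWED_N:
            raise ValidationError(
                f"n_clonotypes must be one of {sorted(ALLOWED_N)}, "
                f"got {self.n_clonotypes}"
            )
        for vocab in (self.v_vocab, self.d_vocab, self.j_vocab):
            if sorted(set(vocab)) != list(vocab):
                raise ValidationError("vocabularies must be sorted and unique")
        names: list[str] = []
        numeric: list[bool] = []
        for slot in range(1, self.n_clonotypes + 1):
            names += [f"c{slot}_fraction", f"c{slot}_cdr3_length"]
            names += [f"c{slot}_kf{k}" for k in range(1, 11)]
            numeric += [True] * NUMERIC_PER_SLOT
            for prefix, vocab in (
                ("v", self.v_vocab), ("d", self.d_vocab), ("j", self.j_vocab)
            ):
                names += [f"c{slot}_{prefix}_{g}" for g in vocab]
                numeric += [False] * len(vocab)
        names += list(REPERTOIRE_BLOCK)
        numeric += [True] * len(REPERTOIRE_BLOCK)
        self.feature_names = names
        self.numeric_mask = np.array(numeric)

    @property
    def per_clonotype_width(self) -> int:
        return (NUMERIC_PER_SLOT + len(self.v_vocab) + len(self.d_vocab)
                + len(self.j_vocab))

    @property
    def width(self) -> int:
        return self.n_clonotypes * self.per_clonotype_width + len(REPERTOIRE_BLOCK)


@dataclass
class FeatureVector:
    """One repertoire's realization of a schema."""

    sample_id: str
    values: np.ndarray
    label: str | None = None


def _top_n(rep: Repertoire, n: int) -> pd.DataFrame:
    return rep.clonotypes.iloc[: min(n, rep.richness)]


def build_schema(
    repertoires: list[Repertoire], n: int, scaling_enabled: bool = False
) -> FeatureSchema:
    """Learn vocabularies (and scaling parameters) from training data.

    Only the top-n clonotypes of the *training* repertoires contribute
    gene names, and scaling statistics are fitted on training vectors
    only — test-set genes or distributions never leak into the schema.
    The result is independent of the order in which repertoires are
    presented.
    """
    if n not in ALLOWED_N:
        raise ValidationError(
            f"n must be one of {sorted(ALLOWED_N)}, got {n}"
        )
    if not repertoires:
        raise ValidationError("need at least one training repertoire")
    v: set[str] = set()
    d: set[str] = set()
    j: set[str] = set()
    for rep in repertoires:
        top = _top_n(rep, n)
        v.update(top["v_gene"])
        d.update(top["d_gene"])
        j.update(top["j_gene"])
    schema = FeatureSchema(
        n_clonotypes=n,
        v_vocab=sorted(v),
        d_vocab=sorted(d),
        j_vocab=sorted(j),
        scaling_enabled=scaling_enabled,
    )
    if scaling_enabled:
        raw = np.vstack([
            _vectorize_unscaled(rep, schema) for rep in repertoires
        ])
        mask = schema.numeric_mask
        mean = np.zeros(schema.width)
        sd = np.ones(schema.width)
        mean[mask] = raw[:, mask].mean(axis=0)
        col_sd = raw[:, mask].std(axis=0)
        col_sd[col_sd == 0] = 1.0  # constant column maps to exactly 0
        sd[mask] = col_sd
        schema.scaling_mean = mean
        schema.scaling_sd = sd
    return schema


def _vectorize_unscaled(rep: Repertoire, schema: FeatureSchema) -> np.ndarray:
    values = np.zeros(schema.width)
    width = schema.per_clonotype_width
    v_index = {g: i for i, g in enumerate(schema.v_vocab)}
    d_index = {g: i for i, g in enumerate(schema.d_vocab)}
    j_index = {g: i for i, g in enumerate(schema.j_vocab)}
    top = _top_n(rep, schema.n_clonotypes)
    for slot, row in enumerate(top.itertuples(index=False)):
        base = slot * width
        values[base] = row.fraction
        values[base + 1] = len(row.cdr3_aa)
        values[base + 2:base + 12] = kidera_descriptor(row.cdr3_aa)
        off = base + NUMERIC_PER_SLOT
        if row.v_gene in v_index:
            values[off + v_index[row.v_gene]] = 1.0
        off += len(schema.v_vocab)
        if row.d_gene in d_index:
            values[off + d_index[row.d_gene]] = 1.0
        off += len(schema.d_vocab)
        if row.j_gene in j_index:
            values[off + j_index[row.j_gene]] = 1.0
    m = compute_metrics(rep)
    values[-4:] = (m.clonality, m.shannon, m.richness, m.shm_fraction)
    return values


def vectorize(rep: Repertoire, schema: FeatureSchema) -> FeatureVector:
    """Encode one repertoire under a fitted schema."""
    values = _vectorize_unscaled(rep, schema)
    if schema.scaling_enabled:
        if schema.scaling_mean is None or schema.scaling_sd is None:
            raise ValidationError("schema has scaling enabled but no parameters")
        values = (values - schema.scaling_mean) / schema.scaling_sd
    return FeatureVector(
        sample_id=rep.sample_id, values=values, label=rep.label or None
    )


def assemble_matrix(
    repertoires: list[Repertoire], schema: FeatureSchema
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature matrix (rows in input order) plus the label vector."""
    vecs = [vectorize(rep, schema) for rep in repertoires]
    X = pd.DataFrame(
        np.vstack([v.values for v in vecs]),
        index=pd.Index([v.sample_id for v in vecs], name="sample_id"),
        columns=schema.feature_names,
    )
    y = pd.Series([v.label for v in vecs], index=X.index, name="label")
    return X, y


def write_matrix(X: pd.DataFrame, y: pd.Series, path) -> None:
    """Write features plus label column as TSV."""
    out = X.copy()
    out.insert(0, "label", y)
    out.to_csv(path, sep="\t", index_label="sample_id")


def read_matrix(path) -> tuple[pd.DataFrame, pd.Series]:
    """Inverse of :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id", comment="#")
    y = df.pop("label")
    return df, y
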