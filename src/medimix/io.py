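"""Count-table and metadata ingestion, validation, and result output.

The data model mirrors the usual amplicon-study layout: a taxa x samples
integer count matrix with one taxonomic lineage per taxon, and a per-sample
clinical metadata table keyed by sample id.  Samples are clustered by
patient; repeated sputum samples from one patient form one cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("medimix")

#: canonical lineage ranks, most-to-least inclusive
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

CLINICAL_STATES = ("baseline", "exacerbation", "treatment", "recovery")
AGGRESSIVENESS_LEVELS = ("mild", "moderate_severe")

_EFFECT_COLUMNS = [
    "contrast",
    "effect_type",
    "mediator",
    "estimate",
    "ci_lower",
    "ci_upper",
    "p_value",
    "p_adjusted",
]


@dataclass
class CountTable:
    """Taxa x samples integer count matrix with per-taxon lineages.

    Parameters
    ----------
    counts : ndarray of shape (n_taxa, n_samples)
        Non-negative integer read counts.
    taxon_ids : list of str
        Unique taxon (OTU or genus) identifiers, one per row.
    lineages : list of tuple of str
        Ordered rank values ``(domain, ..., genus)`` per taxon; missing
        trailing ranks are padded with the empty string.
    sample_ids : list of str
        Unique sample identifiers, one per column.
    """

    counts: np.ndarray
    taxon_ids: list = field(default_factory=list)
    lineages: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D taxa x samples matrix")
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.lineages = [_pad_lineage(l) for l in self.lineages]
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self):
        n_taxa, n_samples = self.counts.shape
        if len(self.taxon_ids) != n_taxa:
            raise ValueError("taxon_ids length does not match counts rows")
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match counts columns")
        if len(self.lineages) != n_taxa:
            raise ValueError("lineages length does not match taxon count")
        dup = _first_duplicate(self.taxon_ids)
        if dup is not None:
            raise ValueError(f"duplicate taxon id: {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValueError(f"duplicate sample id: {dup!r}")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite values")
        if np.issubdtype(self.counts.dtype, np.floating):
            frac = self.counts != np.floor(self.counts)
            if frac.any():
                r, c = np.argwhere(frac)[0]
                raise ValueError(
                    f"non-integer count at taxon {self.taxon_ids[r]!r}, "
                    f"sample {self.sample_ids[c]!r}: {self.counts[r, c]}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            r, c = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at taxon {self.taxon_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}: {self.counts[r, c]}"
            )

    # -- convenience ------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def depths(self) -> np.ndarray:
        """Per-sample read depth (column sums)."""
        return self.counts.sum(axis=0)

    def rank_values(self, rank: str) -> list:
        """Lineage value at ``rank`` for every taxon ('' when absent)."""
        i = RANKS.index(rank)
        return [lin[i] for lin in self.lineages]

    def select_taxa(self, mask) -> "CountTable":
        idx = np.flatnonzero(np.asarray(mask))
        return CountTable(
            self.counts[idx],
            [self.taxon_ids[i] for i in idx],
            [self.lineages[i] for i in idx],
            list(self.sample_ids),
        )

    def select_samples(self, ids) -> "CountTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return CountTable(
            self.counts[:, idx],
            list(self.taxon_ids),
            list(self.lineages),
            [self.sample_ids[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)
        df.index.name = "taxon_id"
        return df


def _pad_lineage(lineage):
    if isinstance(lineage, str):
        parts = [p.strip() for p in lineage.split(";")]
    else:
        parts = [str(p).strip() for p in lineage]
    parts = parts[: len(RANKS)]
    parts += [""] * (len(RANKS) - len(parts))
    return tuple(parts)


def _first_duplicate(items):
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_count_table(path, fmt: str = "tsv", transposed: bool = False) -> CountTable:
    """Read a count table from TSV or BIOM (HDF5) into a :class:`CountTable`.

    TSV dialect: taxa as rows, first column the taxon id, remaining columns
    samples; an optional last column named ``lineage`` carries
    semicolon-separated ranks.  ``transposed=True`` accepts samples-as-rows
    input and flips it.
    """
    if fmt not in ("tsv", "biom"):
        raise ValueError(f"unsupported count-table format: {fmt!r}")
    if fmt == "biom":
        return _read_biom(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dup = _first_duplicate(header[1:])  # pandas would mangle duplicates
    if dup is not None:
        raise ValueError(f"duplicate sample id: {dup!r}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    lineage_col = next((c for c in df.columns if c.lower() == "lineage"), None)
    if lineage_col is not None:
        lineages = df[lineage_col].fillna("").tolist()
        df = df.drop(columns=[lineage_col])
    else:
        lineages = [""] * len(df)
    counts = df.apply(pd.to_numeric).to_numpy()
    table = CountTable(
        counts if not transposed else counts.T,
        list(df.index) if not transposed else list(df.columns),
        lineages,
        list(df.columns) if not transposed else list(df.index),
    )
    return table


def _read_biom(path) -> CountTable:
    """Minimal BIOM 2.1 (HDF5) reader: CSR observation matrix + taxonomy."""
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as f:
        obs_ids = [_decode(x) for x in f["observation/ids"][:]]
        sample_ids = [_decode(x) for x in f["sample/ids"][:]]
        data = f["observation/matrix/data"][:]
        indices = f["observation/matrix/indices"][:]
        indptr = f["observation/matrix/indptr"][:]
        mat = sparse.csr_matrix(
            (data, indices, indptr), shape=(len(obs_ids), len(sample_ids))
        )
        lineages = [""] * len(obs_ids)
        if "observation/metadata/taxonomy" in f:
            tax = f["observation/metadata/taxonomy"][:]
            lineages = [
                ";".join(_strip_rank_prefix(_decode(t)) for t in row) for row in tax
            ]
    return CountTable(mat.toarray(), obs_ids, lineages, sample_ids)


def _decode(x):
    return x.decode() if isinstance(x, bytes) else str(x)


def _strip_rank_prefix(name: str) -> str:
    # greengenes-style "g__Streptococcus" -> "Streptococcus"
    if len(name) > 3 and name[1:3] == "__":
        return name[3:]
    return name


def write_count_table(table: CountTable, path):
    """Write a :class:`CountTable` as TSV (inverse of :func:`read_count_table`)."""
    df = table.to_frame()
    df["lineage"] = [";".join(l).rstrip(";") for l in table.lineages]
    df.to_csv(path, sep="\t")


def read_metadata(path, sep=None) -> pd.DataFrame:
    """Read and validate per-sample metadata (CSV or TSV).

    Required columns: ``sample_id, cluster_id, clinical_state, age,
    fev1_pct``; ``aggressiveness`` is optional.  Categorical labels are
    normalized case-insensitively ('moderate/severe' is accepted as an
    alias of 'moderate_severe').  Returns a DataFrame indexed by sample_id
    with an ``observation_index`` counter within each cluster.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "cluster_id": str})
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    required = ["sample_id", "cluster_id", "clinical_state", "age", "fev1_pct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing required column(s): {missing}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    dup = _first_duplicate(df["sample_id"].tolist())
    if dup is not None:
        raise ValueError(f"duplicate sample id in metadata: {dup!r}")
    df["cluster_id"] = df["cluster_id"].astype(str)

    df["clinical_state"] = df["clinical_state"].map(_normalize_label)
    bad = sorted(set(df["clinical_state"]) - set(CLINICAL_STATES))
    if bad:
        raise ValueError(
            f"unknown clinical_state label(s): {bad}; allowed: {CLINICAL_STATES}"
        )
    if "aggressiveness" in df.columns:
        notna = df["aggressiveness"].notna()
        df.loc[notna, "aggressiveness"] = df.loc[notna, "aggressiveness"].map(
            _normalize_label
        )
        bad = sorted(set(df.loc[notna, "aggressiveness"]) - set(AGGRESSIVENESS_LEVELS))
        if bad:
            raise ValueError(
                f"unknown aggressiveness label(s): {bad}; "
                f"allowed: {AGGRESSIVENESS_LEVELS}"
            )
    for col, lo in (("age", 0.0), ("fev1_pct", 0.0)):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ValueError(f"missing or non-numeric {col} in metadata")
        if (vals <= lo).any():
            bad_ids = df.loc[vals <= lo, "sample_id"].tolist()
            raise ValueError(f"{col} must be > {lo}; offending sample(s): {bad_ids}")
        df[col] = vals
    df = df.set_index("sample_id", drop=False)
    df["observation_index"] = df.groupby("cluster_id").cumcount()
    return df


def _normalize_label(x):
    s = str(x).strip().lower().replace("/", "_").replace("-", "_").replace(" ", "_")
    return s


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align(table: CountTable, meta: pd.DataFrame):
    """Restrict a count table and metadata to their shared samples.

    Ordering follows the count table's column order.  Dropped samples are
    logged; an empty intersection is an error.
    """
    table_ids = set(table.sample_ids)
    meta_ids = set(meta.index)
    shared = [s for s in table.sample_ids if s in meta_ids]
    if not shared:
        raise ValueError("no samples shared between count table and metadata")
    dropped_counts = len(table_ids - meta_ids)
    dropped_meta = len(meta_ids - table_ids)
    if dropped_counts or dropped_meta:
        logger.warning(
            "align: dropped %d count-table sample(s) and %d metadata sample(s) "
            "outside the shared set of %d",
            dropped_counts,
            dropped_meta,
            len(shared),
        )
    return table.select_samples(shared), meta.loc[shared]


# ---------------------------------------------------------------------------
# effect tables
# ---------------------------------------------------------------------------

def make_effect_table(rows) -> pd.DataFrame:
    """Assemble effect rows into the canonical result table.

    Each row is a mapping with the keys in ``_EFFECT_COLUMNS``; missing
    optional keys default to NaN/''.
    """
    df = pd.DataFrame(list(rows), columns=_EFFECT_COLUMNS)
    df["mediator"] = df["mediator"].fillna("")
    _check_effect_table(df)
    return df


def _check_effect_table(df: pd.DataFrame):
    bad = df["ci_lower"] > df["ci_upper"]
    if bad.fillna(False).any():
        raise ValueError("ci_lower exceeds ci_upper in effect table")
    for col in ("p_value", "p_adjusted"):
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{col} outside [0, 1] in effect table")


def write_effect_table(effects: pd.DataFrame, path):
    """Write an effect table as TSV with floats at 6 significant digits."""
    _check_effect_table(effects)
    effects.to_csv(path, sep="\t", index=False, float_format="%.6g", columns=_EFFECT_COLUMNS)


def read_effect_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contrast": str, "effect_type": str})
    df["mediator"] = df["mediator"].fillna("").astype(str)
    return df
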