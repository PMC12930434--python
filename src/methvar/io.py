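"""Input/output for region-based methylation analysis.

Reads the three input tables (M-value matrix, region map, sample design),
performs the beta-to-M transform, and writes/reads the results table in a
stable tab-delimited dialect (UTF-8, LF line endings, ``#`` comment header).

M-values are log2 odds of methylation: ``M = log2(beta / (1 - beta))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

#: Columns of the results table, in their fixed on-disk order.
RESULT_COLUMNS = [
    "region_id", "n_cpgs", "delta_hat", "se_delta", "kappa_hat", "se_kappa",
    "sigma_b2", "p_mean", "p_var", "p_joint", "fdr_mean", "fdr_var",
    "fdr_joint", "call", "converged", "n_iter",
]


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dup[:5]}")


@dataclass
class MValueMatrix:
    """CpG-by-sample matrix of logit-scale methylation values."""

    cpg_ids: list
    sample_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.cpg_ids = list(self.cpg_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.cpg_ids, "CpG ids")
        _check_unique(self.sample_ids, "sample ids")
        if self.values.shape != (len(self.cpg_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cpg_ids)} CpGs x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite M-value at CpG {self.cpg_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r} (missing cells are not supported)"
            )
        self._cpg_index = {c: k for k, c in enumerate(self.cpg_ids)}

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def rows(self, cpg_ids) -> np.ndarray:
        """Row indices of the given CpG ids, in the given order."""
        try:
            return np.array([self._cpg_index[c] for c in cpg_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise ValidationError(f"CpG {exc.args[0]!r} not present in matrix") from exc

    def subset_samples(self, sample_ids) -> "MValueMatrix":
        idx = {s: k for k, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return MValueMatrix(self.cpg_ids, list(sample_ids), self.values[:, cols])


@dataclass
class RegionMap:
    """Assignment of CpG ids to named regions, preserving within-region order."""

    region_ids: list
    cpgs_by_region: dict

    def __post_init__(self):
        self.region_ids = list(self.region_ids)
        _check_unique(self.region_ids, "region ids")
        seen = {}
        for rid in self.region_ids:
            cpgs = list(self.cpgs_by_region[rid])
            if len(cpgs) < 1:
                raise ValidationError(f"region {rid!r} has no CpGs")
            for c in cpgs:
                if c in seen:
                    raise ValidationError(
                        f"CpG {c!r} mapped to two regions: {seen[c]!r} and {rid!r}"
                    )
                seen[c] = rid

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def cpgs(self, region_id) -> list:
        return list(self.cpgs_by_region[region_id])

    def sizes(self) -> dict:
        return {r: len(self.cpgs_by_region[r]) for r in self.region_ids}


@dataclass
class SampleDesign:
    """Per-sample phenotype G and covariate matrix (intercept prepended)."""

    sample_ids: list
    phenotype: np.ndarray
    covariates: np.ndarray = None
    covariate_names: list = field(default_factory=lambda: ["intercept"])

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        _check_unique(self.sample_ids, "sample ids")
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        n = len(self.sample_ids)
        if self.phenotype.shape != (n,):
            raise ValidationError("phenotype length does not match sample ids")
        if not np.all(np.isfinite(self.phenotype)):
            raise ValidationError("phenotype contains non-finite values")
        if np.unique(self.phenotype).size < 2:
            raise ValidationError("phenotype has one level")
        if self.covariates is None:
            self.covariates = np.ones((n, 1))
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.shape[0] != n:
            raise ValidationError("covariate rows do not match sample ids")
        if len(self.covariate_names) != self.covariates.shape[1]:
            raise ValidationError("covariate_names length mismatch")
        full = np.column_stack([self.covariates, self.phenotype])
        if np.linalg.matrix_rank(full) < full.shape[1]:
            raise ValidationError(
                "covariate matrix (with intercept and phenotype) is rank deficient"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids) -> "SampleDesign":
        idx = {s: k for k, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return SampleDesign(
            list(sample_ids), self.phenotype[rows], self.covariates[rows],
            list(self.covariate_names),
        )


# ---------------------------------------------------------------------------
# beta -> M transform
# ---------------------------------------------------------------------------

def beta_to_m(beta, epsilon: float = 1e-6):
    """log2 odds of a methylation proportion, with clamping away from {0, 1}.

    Parameters
    ----------
    beta
        Methylation proportion(s) in [0, 1]; scalar or array.
    epsilon
        Clamp bound in (0, 0.5); beta is clipped to [epsilon, 1 - epsilon]
        so M-values stay finite at the boundaries.
    """
    if not (0.0 < epsilon < 0.5):
        raise ValidationError(f"epsilon must be in (0, 0.5), got {epsilon}")
    arr = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(arr)) or arr.min() < 0.0 or arr.max() > 1.0:
        raise ValidationError("beta values must be finite and in [0, 1]")
    b = np.clip(arr, epsilon, 1.0 - epsilon)
    out = np.log2(b / (1.0 - b))
    return float(out) if np.isscalar(beta) else out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    m = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-m))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def read_mvalue_matrix(path, transform_beta: bool = False,
                       epsilon: float = 1e-6) -> MValueMatrix:
    """Read a tab-delimited CpG-by-sample matrix (first column = CpG id).

    With ``transform_beta`` the cells are treated as beta-values in [0, 1]
    and passed through :func:`beta_to_m`.
    """
    df = _read_tsv(path, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicated CpG id(s) in {path}: {dup[:5]}")
    vals = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(np.isnan(vals) & ~df.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"non-numeric cell in {path} at CpG {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    if np.isnan(vals).any():
        i, j = np.argwhere(np.isnan(vals))[0]
        raise ValidationError(
            f"missing cell in {path} at CpG {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    if transform_beta:
        vals = beta_to_m(vals, epsilon=epsilon)
    return MValueMatrix(df.index.tolist(), df.columns.tolist(), vals)


def read_region_map(path_or_bed, manifest=None) -> RegionMap:
    """Read a region map.

    Two dialects are supported:

    * a two-column tab-delimited table with header ``cpg_id<TAB>region_id``;
    * a BED file (3+ columns, 0-based half-open intervals) together with a
      CpG position ``manifest`` — a table with header
      ``cpg_id<TAB>chrom<TAB>position``. Positions default to 0-based; a
      leading comment line ``#coords=1-based`` switches the convention.
      A CpG joins a region when its chromosome matches and
      ``start <= position < end``.
    """
    if manifest is None:
        df = _read_tsv(path_or_bed, dtype=str)
        if df.shape[1] < 2:
            raise ValidationError("region map table needs two columns (cpg_id, region_id)")
        cpg_col, reg_col = df.columns[:2]
        pairs = df[[cpg_col, reg_col]].dropna()
        region_ids, cpgs_by_region = [], {}
        for cpg, rid in pairs.itertuples(index=False):
            if rid not in cpgs_by_region:
                region_ids.append(rid)
                cpgs_by_region[rid] = []
            cpgs_by_region[rid].append(cpg)
        return RegionMap(region_ids, cpgs_by_region)

    bed = pd.read_csv(path_or_bed, sep="\t", comment="#", header=None, dtype=str)
    if bed.shape[1] < 3:
        raise ValidationError("BED file needs at least 3 columns")
    bed = bed.iloc[:, :4] if bed.shape[1] >= 4 else bed
    chroms = bed.iloc[:, 0].astype(str).to_numpy()
    starts = bed.iloc[:, 1].astype(int).to_numpy()
    ends = bed.iloc[:, 2].astype(int).to_numpy()
    if bed.shape[1] >= 4:
        names = bed.iloc[:, 3].astype(str).tolist()
    else:
        names = [f"{c}:{s}-{e}" for c, s, e in zip(chroms, starts, ends)]

    one_based = False
    with open(manifest) as fh:
        first = fh.readline()
    if first.startswith("#") and "coords=1-based" in first:
        one_based = True
    man = _read_tsv(manifest, dtype={0: str, 1: str})
    if man.shape[1] < 3:
        raise ValidationError("manifest needs columns cpg_id, chrom, position")
    man_cpg = man.iloc[:, 0].astype(str).to_numpy()
    man_chrom = man.iloc[:, 1].astype(str).to_numpy()
    man_pos = man.iloc[:, 2].astype(int).to_numpy()
    if one_based:
        man_pos = man_pos - 1

    region_ids, cpgs_by_region = [], {}
    n_empty = 0
    for chrom, start, end, name in zip(chroms, starts, ends, names):
        mask = (man_chrom == chrom) & (man_pos >= start) & (man_pos < end)
        hit = man_cpg[mask]
        # preserve manifest order within the region
        order = np.argsort(man_pos[mask], kind="stable")
        hit = list(hit[order])
        if not hit:
            n_empty += 1
            continue
        region_ids.append(name)
        cpgs_by_region[name] = hit
    if n_empty:
        logger.info("dropped %d empty region(s) with no mapped CpGs", n_empty)
    return RegionMap(region_ids, cpgs_by_region)


def read_sample_design(path, phenotype_col: str,
                       covariate_cols=()) -> SampleDesign:
    """Read a tab-delimited sample table (first column = sample id)."""
    df = _read_tsv(path, index_col=0)
    if phenotype_col not in df.columns:
        raise ValidationError(f"phenotype column {phenotype_col!r} not in {path}")
    missing = [c for c in covariate_cols if c not in df.columns]
    if missing:
        raise ValidationError(f"covariate column(s) {missing} not in {path}")
    pheno = pd.to_numeric(df[phenotype_col], errors="raise").to_numpy(dtype=float)
    n = len(df)
    cov = np.ones((n, 1))
    names = ["intercept"]
    for c in covariate_cols:
        cov = np.column_stack([cov, pd.to_numeric(df[c]).to_numpy(dtype=float)])
        names.append(c)
    if np.linalg.matrix_rank(cov) < cov.shape[1]:
        raise ValidationError("covariates rank deficient after intercept prepend")
    return SampleDesign(df.index.astype(str).tolist(), pheno, cov, names)


def align(matrix: MValueMatrix, design: SampleDesign, min_samples: int = 3):
    """Align a matrix and design on their common samples (matrix column order).

    Samples absent from either side are dropped with a logged warning; fewer
    than ``min_samples`` common samples is a hard error.
    """
    common = [s for s in matrix.sample_ids if s in set(design.sample_ids)]
    dropped = (set(matrix.sample_ids) | set(design.sample_ids)) - set(common)
    if dropped:
        logger.warning("dropping %d sample(s) absent from matrix or design: %s",
                       len(dropped), sorted(dropped)[:10])
    if len(common) < min_samples:
        raise ValidationError(
            f"only {len(common)} samples shared between matrix and design "
            f"(need >= {min_samples})"
        )
    return matrix.subset_samples(common), design.subset(common)


# ---------------------------------------------------------------------------
# results table
# ---------------------------------------------------------------------------

def write_results(results: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a results table as TSV with >=10 significant digits.

    ``metadata`` key/value pairs are emitted as leading ``# key=value``
    comment lines.
    """
    cols = RESULT_COLUMNS + [c for c in results.columns if c not in RESULT_COLUMNS]
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValidationError(f"results table missing column(s): {missing}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        results[cols].to_csv(fh, sep="\t", index=False, float_format="%.12g",
                             lineterminator="\n")


def read_results(path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`."""
    df = _read_tsv(path)
    for c in ("converged",):
        if c in df.columns and df[c].dtype == object:
            df[c] = df[c].astype(str).str.lower().isin(("true", "1"))
    return df
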