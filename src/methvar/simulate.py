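"""Synthetic region-structured methylation data with known ground truth.

Each region is a block of contiguous CpGs; for sample ``i`` in group
``g in {0, 1}`` the CpG vector is drawn from a multivariate normal

    MVN( mu0 + mean_effect * g,  sigma2_g * [(1 - rho) I + rho J] )

with compound-symmetry correlation ``rho`` and group variance
``sigma2_g = base_sd^2 * var_fold^g``, samples independent. Signal regions
receive the mean effect (DMR/DVMR scenarios) and/or the variance fold
(VMR/DVMR); null regions receive neither. Defaults follow the benchmark
design this generator emulates: 10,000 regions with 10% true signals, a
mean effect of 0.7 M-value units, a 2.5-fold group-2 variance inflation, a
30%/70% case-control split at N = 100, rho = 0.5 and unit baseline SD.

Every region draws from its own counter-based RNG stream derived from
(seed, region index), so datasets are a pure function of their config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import MValueMatrix, RegionMap, SampleDesign

__all__ = ["ScenarioConfig", "SimDataset", "simulate_region",
           "simulate_study", "permute_labels"]

SCENARIOS = ("null", "DMR", "VMR", "DVMR")


@dataclass
class ScenarioConfig:
    """Generative settings for one simulated study."""

    n_regions: int = 10_000
    prop_signal: float = 0.1
    scenario: str = "DMR"
    mean_effect: float = 0.7      # M-value shift in group 1 (cases)
    var_fold: float = 2.5         # group-1 ("group 2" of the design) variance multiplier
    N: int = 100
    group_props: tuple = (0.7, 0.3)   # (P[G=0], P[G=1]); cases carry the effects
    n_cpgs_per_region: tuple = (3, 10)  # inclusive range, or (k, k) for fixed k
    rho: float = 0.5
    base_sd: float = 1.0
    mu0: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"scenario must be one of {SCENARIOS}")
        if not (0.0 <= self.prop_signal <= 1.0):
            raise ValidationError("prop_signal must be in [0, 1]")
        if not (0.0 <= self.rho < 1.0):
            raise ValidationError("rho must be in [0, 1)")
        if self.var_fold < 1.0:
            raise ValidationError("var_fold must be >= 1")
        if abs(sum(self.group_props) - 1.0) > 1e-9:
            raise ValidationError("group_props must sum to 1")

    @property
    def n_signal(self) -> int:
        return int(round(self.n_regions * self.prop_signal))


@dataclass
class SimDataset:
    """A simulated study: data triplet plus the per-region truth table."""

    matrix: MValueMatrix
    regions: RegionMap
    design: SampleDesign
    truth: pd.DataFrame
    config: ScenarioConfig = None

    def metadata(self) -> dict:
        return asdict(self.config) if self.config else {}


def simulate_region(n_cpgs: int, N: int, group_labels, rho: float,
                    base_sd: float, mean_effect: float, var_fold: float,
                    rng: np.random.Generator, mu0: float = 0.0) -> np.ndarray:
    """Draw one region's (n_cpgs x N) M-value block.

    Compound symmetry is generated exactly as a shared per-sample factor:
    ``y_ij = mu_g + sigma_g * (sqrt(rho) u_i + sqrt(1 - rho) z_ij)``.
    """
    g = np.asarray(group_labels, dtype=float)
    if g.shape != (N,):
        raise ValidationError("group_labels must have length N")
    sigma = base_sd * np.power(var_fold, g / 2.0)          # (N,)
    u = rng.standard_normal(N)
    z = rng.standard_normal((N, n_cpgs))
    block = (mu0 + mean_effect * g)[:, None] + sigma[:, None] * (
        np.sqrt(rho) * u[:, None] + np.sqrt(1.0 - rho) * z)
    return block.T                                          # (n_cpgs, N)


def _region_rng(seed: int, r: int) -> np.random.Generator:
    return np.random.default_rng([seed, 0, r])


def simulate_study(cfg: ScenarioConfig) -> SimDataset:
    """Generate a full study per the scenario config (pure function of cfg)."""
    N = cfg.N
    n0 = int(np.floor(N * cfg.group_props[0]))
    n1 = N - n0
    if min(n0, n1) < 2:
        raise ValidationError("each group needs at least 2 samples")
    labels = np.concatenate([np.zeros(n0), np.ones(n1)])
    np.random.default_rng([cfg.seed, 1]).shuffle(labels)

    lo, hi = cfg.n_cpgs_per_region
    n_signal = cfg.n_signal
    want_mean = cfg.scenario in ("DMR", "DVMR")
    want_var = cfg.scenario in ("VMR", "DVMR")

    sample_ids = [f"S{i:05d}" for i in range(N)]
    region_ids, cpgs_by_region, truth_rows, blocks, cpg_ids = [], {}, [], [], []
    for r in range(cfg.n_regions):
        rng = _region_rng(cfg.seed, r)
        n_cpgs = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        is_signal = (r < n_signal) and cfg.scenario != "null"
        delta = cfg.mean_effect if (is_signal and want_mean) else 0.0
        fold = cfg.var_fold if (is_signal and want_var) else 1.0
        block = simulate_region(n_cpgs, N, labels, cfg.rho, cfg.base_sd,
                                delta, fold, rng, mu0=cfg.mu0)
        rid = f"R{r:06d}"
        ids = [f"cg{r:06d}_{j:02d}" for j in range(n_cpgs)]
        region_ids.append(rid)
        cpgs_by_region[rid] = ids
        cpg_ids.extend(ids)
        blocks.append(block)
        truth_rows.append({
            "region_id": rid, "is_signal": bool(is_signal),
            "scenario": cfg.scenario, "true_delta": delta,
            "true_log_varfold": float(np.log(fold)),
        })

    matrix = MValueMatrix(cpg_ids, sample_ids, np.vstack(blocks))
    regions = RegionMap(region_ids, cpgs_by_region)
    design = SampleDesign(sample_ids, labels)
    truth = pd.DataFrame(truth_rows)
    return SimDataset(matrix, regions, design, truth, cfg)


def permute_labels(design: SampleDesign, seed: int) -> SampleDesign:
    """Uniformly permute the phenotype vector (covariates untouched)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(design.n_samples)
    return SampleDesign(design.sample_ids, design.phenotype[perm],
                        design.covariates, list(design.covariate_names))
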