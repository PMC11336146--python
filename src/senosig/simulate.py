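"""Synthetic multi-dataset cohorts with known ground truth.

The generator emulates an integrated, multi-study microarray cohort of the
kind assembled from public repositories: log-normal (right-skewed,
MAS5-like) expression intensities on heterogeneous per-gene scales, per-
dataset multiplicative batch shifts, proportional-hazards survival driven by
a minority of risk/protective genes, independent administrative censoring
calibrated to a target rate, and every array scaled to mean intensity 1000.

Defaults mirror the integrated cohort the analysis targets: 1130 samples
over 10 datasets, ~24% relapse events (censoring 0.76), follow-up on the
months scale with a mean around 50, and 40 risk + 40 protective genes at
log-hazard +/-0.5 among 200.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix

#: Default per-dataset sample sizes (total 1130 over 10 datasets).
DEFAULT_DATASET_SIZES = (229, 177, 157, 130, 110, 96, 83, 62, 49, 37)

#: Clinical covariate category frequencies used by default (fractions over
#: non-missing records of an integrated colon-cancer cohort).
DEFAULT_COVARIATE_FREQS: dict[str, dict[str, float]] = {
    "sex": {"female": 0.4692, "male": 0.5308},
    "t_stage": {"1": 0.0225, "2": 0.0962, "3": 0.6721, "4": 0.2090},
    "n_stage": {"0": 0.5288, "1": 0.2840, "2": 0.1790, "3": 0.0082},
    "m_stage": {"0": 0.9331, "1": 0.0669},
    "stage": {"1": 0.0869, "2": 0.4865, "3": 0.3871, "4": 0.0396},
    "grade": {"1": 0.1257, "2": 0.7432, "3": 0.1311},
    "location": {"proximal": 0.4275, "distal": 0.5725},
    "msi": {"stable": 0.2063, "stable_or_low": 0.6726, "high": 0.1211},
}

#: Default per-feature missingness (fraction of samples with a null cell),
#: matching how sparsely such covariates are typically available.
DEFAULT_MISSINGNESS: dict[str, float] = {
    "sex": 0.18, "t_stage": 0.57, "n_stage": 0.57, "m_stage": 0.55,
    "stage": 0.08, "grade": 0.84, "location": 0.30, "msi": 0.41,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the cohort generator; defaults are the study-like cohort."""

    n_samples: tuple[int, ...] = DEFAULT_DATASET_SIZES
    n_genes: int = 200
    n_risk: int = 40
    n_protective: int = 40
    beta_risk: float = 0.5
    beta_protective: float = -0.5
    baseline: str = "exponential"       # or "weibull"
    baseline_rate: float = 0.00042      # per month; ~50-month mean follow-up at defaults
    weibull_shape: float = 1.0
    censoring_rate: float = 0.76        # target censored fraction
    batch_shift_sd: float = 0.1         # log-scale per-dataset, per-gene shift
    log_mean_range: tuple[float, float] = (np.log(50.0), np.log(4000.0))
    log_sd: float = 0.5                 # within-gene log-intensity spread
    target_mean: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_risk + self.n_protective > self.n_genes:
            raise ValueError("effect genes exceed n_genes")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")
        if min(self.n_samples) < 1 or self.n_genes < 1:
            raise ValueError("sizes must be positive")
        if self.baseline not in ("exponential", "weibull"):
            raise ValueError(f"unknown baseline {self.baseline!r}")
        if self.baseline_rate <= 0 or self.weibull_shape <= 0:
            raise ValueError("baseline scale/shape must be positive")
        if self.batch_shift_sd < 0 or self.log_sd <= 0 or self.target_mean <= 0:
            raise ValueError("scales must be positive")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one simulated cohort."""

    betas: pd.Series            # gene_id -> true log-hazard per SD
    signs: pd.Series            # gene_id -> -1/0/+1
    eta: pd.Series              # sample_id -> true linear predictor
    realized_censoring: float
    dataset_ids: tuple[str, ...]

    def to_tsv(self, path) -> None:
        pd.DataFrame({"gene_id": self.betas.index, "beta": self.betas.to_numpy(),
                      "sign": self.signs.to_numpy()}).to_csv(
            path, sep="\t", index=False, float_format="%.10g")


class CensoringCalibrationError(RuntimeError):
    pass


def _calibrate_censor_window(
    t_latent: np.ndarray, u: np.ndarray, target_event: float
) -> float:
    """Bisection on the administrative-censoring window upper bound so the
    realized event fraction matches ``target_event`` (censor times are
    window * u, u ~ U(0,1))."""
    def event_frac(c: float) -> float:
        return float(np.mean(t_latent <= c * u))

    lo, hi = 0.0, float(np.median(t_latent)) + 1.0
    for _ in range(200):
        if event_frac(hi) >= target_event:
            break
        hi *= 2.0
        if not np.isfinite(hi):
            raise CensoringCalibrationError(
                f"cannot reach event fraction {target_event}: "
                f"max achievable ~{event_frac(hi / 2):.3f}"
            )
    else:
        raise CensoringCalibrationError("bisection bracket not found")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if event_frac(mid) >= target_event:
            hi = mid
        else:
            lo = mid
    return hi


def simulate_cohort(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[ExpressionMatrix, ClinicalTable, SyntheticTruth]:
    """Draw one cohort.  Identical config (including seed) gives identical
    output, bit for bit.

    The hazard acts on within-dataset standardized expression, so the true
    effect sizes are scale-free and the per-dataset batch shifts cancel in
    the risk model while still distorting the raw matrix the analysis sees.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_total = int(sum(cfg.n_samples))
    gene_ids = [f"g{j + 1:04d}" for j in range(cfg.n_genes)]
    betas = np.zeros(cfg.n_genes)
    betas[: cfg.n_risk] = cfg.beta_risk
    betas[cfg.n_risk: cfg.n_risk + cfg.n_protective] = cfg.beta_protective
    mu = rng.uniform(*cfg.log_mean_range, size=cfg.n_genes)
    dataset_ids = tuple(f"ds{k + 1:02d}" for k in range(len(cfg.n_samples)))
    raw_blocks, eta_blocks, sample_ids, ds_col = [], [], [], []
    for ds, n_d in zip(dataset_ids, cfg.n_samples):
        shift = rng.normal(0.0, cfg.batch_shift_sd, size=cfg.n_genes)
        log_x = mu + shift + rng.normal(0.0, cfg.log_sd, size=(n_d, cfg.n_genes))
        x = np.exp(log_x)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        z = (x - x.mean(axis=0)) / sd
        raw_blocks.append(x)
        eta_blocks.append(z @ betas)
        sample_ids.extend(f"{ds}_s{i + 1:04d}" for i in range(n_d))
        ds_col.extend([ds] * n_d)
    raw = np.vstack(raw_blocks)
    eta = np.concatenate(eta_blocks)
    # proportional-hazards event times
    u_event = rng.uniform(size=n_total)
    rate = cfg.baseline_rate * np.exp(eta)
    if cfg.baseline == "exponential":
        t_latent = -np.log(u_event) / rate
    else:
        t_latent = (-np.log(u_event) / rate) ** (1.0 / cfg.weibull_shape)
    # independent administrative censoring calibrated to the target rate
    if cfg.censoring_rate == 0:
        time, event = t_latent, np.ones(n_total, dtype=int)
    else:
        u_cens = rng.uniform(size=n_total)
        window = _calibrate_censor_window(t_latent, u_cens, 1.0 - cfg.censoring_rate)
        c_time = window * u_cens
        event = (t_latent <= c_time).astype(int)
        time = np.where(event == 1, t_latent, c_time)
    time = np.maximum(time, 1e-9)  # strictly positive follow-up
    # per-array scaling to the target mean
    scaled = raw * (cfg.target_mean / raw.mean(axis=1))[:, None]
    expr = ExpressionMatrix(
        pd.DataFrame(scaled, index=pd.Index(sample_ids, name="sample_id"),
                     columns=gene_ids)
    )
    clin = ClinicalTable(
        pd.DataFrame(
            {"sample_id": sample_ids, "time": time, "event": event,
             "dataset_id": ds_col}
        )
    )
    truth = SyntheticTruth(
        betas=pd.Series(betas, index=gene_ids, name="beta"),
        signs=pd.Series(np.sign(betas).astype(int), index=gene_ids, name="sign"),
        eta=pd.Series(eta, index=sample_ids, name="eta"),
        realized_censoring=float(1.0 - np.mean(event)),
        dataset_ids=dataset_ids,
    )
    return expr, clin, truth


def simulate_clinical_covariates(
    clin: ClinicalTable,
    freqs: Optional[dict[str, dict[str, float]]] = None,
    missingness: Optional[dict[str, float]] = None,
    confound_stage: bool = False,
    eta: Optional[pd.Series] = None,
    seed: int = 0,
) -> ClinicalTable:
    """Attach categorical clinical covariates to a simulated cohort.

    Covariates are drawn independently of survival by default.  With
    ``confound_stage`` the pathological stage instead tracks the true
    log-hazard ``eta`` (quartile binning plus label noise), creating a
    genuine confounder for multivariate checks.  Per-feature missingness is
    injected at the given rates.
    """
    freqs = dict(DEFAULT_COVARIATE_FREQS if freqs is None else freqs)
    missingness = dict(DEFAULT_MISSINGNESS if missingness is None else missingness)
    for name, rate in missingness.items():
        if not (0 <= rate < 1):
            raise ValueError(f"missingness for {name!r} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(clin)
    df = clin.data.reset_index().copy()
    for name, levels in freqs.items():
        labels = list(levels)
        p = np.asarray([levels[l] for l in labels], dtype=float)
        p = p / p.sum()
        draw = rng.choice(labels, size=n, p=p)
        if confound_stage and name == "stage":
            if eta is None:
                raise ValueError("confound_stage requires the true eta")
            e = eta.loc[df["sample_id"]].to_numpy()
            q = np.quantile(e, [0.25, 0.5, 0.75])
            ordinal = np.digitize(e, q)  # 0..3
            noisy = np.clip(ordinal + rng.integers(-1, 2, size=n), 0, 3)
            draw = np.asarray(["1", "2", "3", "4"])[noisy]
        rate = missingness.get(name, 0.0)
        if rate > 0:
            draw = draw.astype(object)
            draw[rng.uniform(size=n) < rate] = None
        df[name] = draw
    return ClinicalTable(df, clin.vocabulary)
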