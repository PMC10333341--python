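"""Synthetic study generator with the statistical structure the pipeline assumes.

Each subject's ROI x time matrix follows a low-rank latent-factor model:
one global factor plus community factors, with AR(1) noise, motion,
white-matter and CSF leakage. Eigenvector centrality responds directly to
the magnitude of a ROI's factor loadings, so group effects are planted as
loading multipliers:

* hub deficit — cases have hub-ROI loadings scaled by ``1 - hub_effect``;
* exposure interaction — within cases, loadings at ``interaction_rois``
  change by ``interaction_slope`` per month on site;
* symptom link — within cases, hub loadings shift with the planted
  weighted symptom index (quartiled subscales times ``symptom_weights``)
  at ``symptom_beta`` EC units per index unit, converted to loading units
  through the calibrated small-effect gain ``EC_PER_LOADING`` (measured by
  simulation at the default configuration; approximate away from it).

Symptom subscales are generated per item (responses 1-3, summed by
:mod:`ecmnet.scid_scales`), so item-level and subscale-level inputs both
exist. Missing exposure months are assigned completely at random. All
randomness flows from ``config.seed``; identical configs give
bit-identical cohorts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.special import expit

from . import scid_scales
from .wqs_regression import quartile_rank, wqs_index

logger = logging.getLogger(__name__)

#: default planted hubs (indices into the bundled 111-region registry):
#: R/L anterior inferior temporal gyrus, R superior parietal lobule,
#: R anterior parahippocampal gyrus, R anterior/posterior temporal fusiform,
#: R caudate, L amygdala, brainstem.
DEFAULT_HUB_ROIS = (13, 61, 65, 81, 84, 85, 101, 104, 110)
#: R anterior parahippocampal gyrus, L amygdala
DEFAULT_INTERACTION_ROIS = (81, 101)
#: left/right anterior inferior temporal gyrus
DEFAULT_BILATERAL_PAIRS = ((13, 61),)

#: small-effect EC change per unit loading multiplier at a planted hub,
#: measured by simulation at the default configuration (see calibration
#: notes in tests); used to convert EC-unit config slopes to loading units.
EC_PER_LOADING = 0.011

# item-response model: logit of per-item success, giving group-separated
# subscale scores with moderate between-scale correlation within group
_ITEM_ALPHA = -2.1
_ITEM_GROUP = 2.8
_ITEM_SHARED = 0.8
_ITEM_SPECIFIC = 0.6


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic study; defaults mirror the target design."""

    n_ptsd: int = 45
    n_control: int = 51
    n_roi: int = 111
    n_volumes: int = 396
    tr_seconds: float = 1.5
    hub_rois: tuple[int, ...] = DEFAULT_HUB_ROIS
    hub_effect: float = 0.35
    interaction_rois: tuple[int, ...] = DEFAULT_INTERACTION_ROIS
    interaction_slope: float = -0.025     # loading units per month
    months_range: tuple[float, float] = (0.0, 10.0)
    n_missing_months: int = 10
    symptom_weights: tuple[float, ...] = (0.65, 0.15, 0.10, 0.10)
    symptom_beta: float = -0.002          # EC units per index unit
    ar_coefficient: float = 0.3
    n_factors: int = 5
    loading_jitter: float = 0.10
    noise_sd: float = 1.0
    factor_ar: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if min(self.n_ptsd, self.n_control, self.n_roi, self.n_volumes) <= 0:
            raise ConfigError("counts must be positive")
        if not 0.0 <= self.hub_effect < 1.0:
            raise ConfigError("hub_effect must lie in [0, 1)")
        for roi in (*self.hub_rois, *self.interaction_rois):
            if not 0 <= roi < self.n_roi:
                raise ConfigError(
                    f"planted ROI index {roi} outside 0..{self.n_roi - 1}"
                )
        if set(self.interaction_rois) - set(self.hub_rois):
            raise ConfigError("interaction_rois must be a subset of hub_rois")
        w = np.asarray(self.symptom_weights, dtype=float)
        if w.size != 4 or w.min() < 0:
            raise ConfigError("symptom_weights must be 4 non-negative values")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError("symptom_weights must sum to 1")
        if self.n_missing_months >= self.n_ptsd + self.n_control:
            raise ConfigError("n_missing_months leaves no usable subjects")
        if not -1.0 < self.ar_coefficient < 1.0:
            raise ConfigError("ar_coefficient must lie in (-1, 1)")

    @property
    def n_subjects(self) -> int:
        return self.n_ptsd + self.n_control

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SubjectTimeSeries:
    """One subject's ROI x time matrix plus confound series."""

    subject_id: str
    data: np.ndarray       # (n_roi, T)
    motion: np.ndarray     # (6, T)
    wm: np.ndarray         # (T,)
    csf: np.ndarray        # (T,)


def _ar1(rng: np.random.Generator, shape: tuple[int, ...],
         phi: float, burn: int = 50) -> np.ndarray:
    """Stationary unit-variance AR(1) series along the last axis."""
    T = shape[-1]
    innov = rng.standard_normal(shape[:-1] + (T + burn,))
    series = signal.lfilter([1.0], [1.0, -phi], innov, axis=-1)
    return series[..., burn:] * np.sqrt(1.0 - phi * phi)


def base_loadings(config: CohortConfig,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """The cohort's base factor loadings: global factor plus communities.

    Drawn from a dedicated seed stream of ``config.seed``, so the same
    matrix is recoverable without generating any time series (used by the
    population-level oracles below).
    """
    if rng is None:
        _, loading_ss, _ = np.random.SeedSequence(config.seed).spawn(3)
        rng = np.random.default_rng(loading_ss)
    n_roi, n_factors = config.n_roi, config.n_factors
    L = np.zeros((n_roi, n_factors))
    L[:, 0] = rng.uniform(0.8, 1.2, size=n_roi)
    if n_factors > 1:
        community = rng.integers(1, n_factors, size=n_roi)
        L[np.arange(n_roi), community] = rng.uniform(0.4, 0.8, size=n_roi)
    return L


def loading_multiplier(
    config: CohortConfig,
    is_case: bool,
    months: float = 0.0,
    symptom_index: float = 0.0,
    symptom_loading: float | None = None,
) -> np.ndarray:
    """Per-ROI loading multiplier encoding every planted effect."""
    mult = np.ones(config.n_roi)
    if is_case:
        if symptom_loading is None:
            symptom_loading = (config.symptom_beta / EC_PER_LOADING
                               if config.symptom_beta != 0.0 else 0.0)
        hub_idx = np.asarray(config.hub_rois, dtype=int)
        inter_idx = np.asarray(config.interaction_rois, dtype=int)
        mult[hub_idx] *= 1.0 - config.hub_effect
        mult[inter_idx] += config.interaction_slope * months
        mult[hub_idx] += symptom_loading * symptom_index
    return np.clip(mult, 0.05, None)


def population_ec(config: CohortConfig, is_case: bool,
                  months: float = 0.0,
                  symptom_index: float = 0.0) -> np.ndarray:
    """Noise-free EC implied by the generative model, via dense eigensolver.

    Builds the population lag-0 and lag-1 ROI covariances of the factor
    model (confound channels are regressed out downstream, so they do not
    enter), applies the AR(1) whitening filter analytically, converts the
    whitened covariance to a +1-shifted correlation adjacency, and returns
    the unit-norm leading eigenvector. Serves as an independent oracle for
    planted-effect sizes in EC units.
    """
    from scipy.linalg import eigh

    L = base_loadings(config)
    mult = loading_multiplier(config, is_case=is_case, months=months,
                              symptom_index=symptom_index)
    gram = (L @ L.T
            + config.loading_jitter ** 2 * config.n_factors
            * np.eye(config.n_roi))
    factor_cov = gram * np.outer(mult, mult)
    noise_cov = config.noise_sd ** 2 * np.eye(config.n_roi)
    c0 = factor_cov + noise_cov
    c1 = config.factor_ar * factor_cov + config.ar_coefficient * noise_cov
    # per-ROI AR(1) estimate on the raw series, then the whitening filter
    # y_t - phi*y_{t-1} applied to the population covariances
    phi = np.diag(c1) / np.diag(c0)
    cov = (c0 * (1.0 + np.outer(phi, phi))
           - c1 * (phi[None, :] + phi[:, None]))
    d = 1.0 / np.sqrt(np.diag(cov))
    adj = cov * np.outer(d, d) + 1.0
    np.fill_diagonal(adj, 2.0)
    _, vecs = eigh(adj)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    return v


def expected_interaction_slope(config: CohortConfig) -> np.ndarray:
    """Planted EC-per-month slope at the interaction ROIs (secant over the
    months range of the population EC curve)."""
    lo, hi = config.months_range
    ec_lo = population_ec(config, is_case=True, months=lo)
    ec_hi = population_ec(config, is_case=True, months=hi)
    idx = np.asarray(config.interaction_rois, dtype=int)
    return (ec_hi[idx] - ec_lo[idx]) / (hi - lo)


def _generate_items(rng: np.random.Generator,
                    ptsd: np.ndarray) -> pd.DataFrame:
    """Item-level responses (1-3) for the four subscales, group-separated."""
    n = ptsd.size
    shared = rng.standard_normal(n)
    cols: dict[str, np.ndarray] = {}
    for spec in scid_scales.SUBSCALES.values():
        specific = rng.standard_normal(n)
        theta = (_ITEM_ALPHA + _ITEM_GROUP * ptsd
                 + _ITEM_SHARED * shared + _ITEM_SPECIFIC * specific)
        p = expit(theta)
        for col in spec.item_columns:
            cols[col] = 1 + rng.binomial(2, p)
    return pd.DataFrame(cols)


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SubjectTimeSeries], pd.DataFrame]:
    """Generate the full synthetic study.

    Returns per-subject time series (with confounds) and a phenotype table
    holding diagnosis, exposure months (NaN where missing), medication and
    MDD indicators, item-level responses, and the summed subscale scores.
    """
    pheno_ss, loading_ss, noise_ss = np.random.SeedSequence(
        config.seed).spawn(3)
    rng = np.random.default_rng(pheno_ss)
    noise_rng = np.random.default_rng(noise_ss)
    n = config.n_subjects
    subject_ids = [f"sub-{i + 1:03d}" for i in range(n)]
    ptsd = np.zeros(n, dtype=int)
    ptsd[: config.n_ptsd] = 1

    lo, hi = config.months_range
    months = rng.uniform(lo, hi, size=n)
    missing = rng.choice(n, size=config.n_missing_months, replace=False)

    mdd = np.where(ptsd == 1, rng.binomial(1, 0.40, size=n), 0)
    psychotropic = rng.binomial(1, np.where(ptsd == 1, 0.40, 0.08))
    opioid = rng.binomial(1, np.where(ptsd == 1, 0.05, 0.04))

    items = _generate_items(rng, ptsd)
    items.insert(0, "subject_id", subject_ids)
    scores = scid_scales.score_all(items)

    pheno = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "ptsd": ptsd,
            "months_on_site": months,
            "mdd": mdd,
            "psychotropic": psychotropic,
            "opioid": opioid,
        }
    )
    pheno.loc[missing, "months_on_site"] = np.nan
    pheno = pheno.merge(scores, on="subject_id").merge(
        items, on="subject_id")

    # planted symptom index within cases: quartiled subscales x weights
    case_mask = ptsd == 1
    w = np.asarray(config.symptom_weights, dtype=float)
    index_centered = np.zeros(n)
    if config.n_ptsd >= 8:
        Q = np.column_stack([
            quartile_rank(pheno.loc[case_mask, name].to_numpy(dtype=float))
            for name in scid_scales.SUBSCALES
        ])
        index_case = wqs_index(w, Q)
        index_centered[case_mask] = index_case - index_case.mean()
    elif config.symptom_beta != 0.0:
        raise ConfigError(
            "symptom_beta needs at least 8 case subjects for quartiling"
        )

    if config.symptom_beta != 0.0 and EC_PER_LOADING == 0.0:
        raise ConfigError(
            "symptom_beta requires a calibrated EC_PER_LOADING gain"
        )
    symptom_loading = (config.symptom_beta / EC_PER_LOADING
                       if config.symptom_beta != 0.0 else 0.0)

    L = base_loadings(config, np.random.default_rng(loading_ss))
    hub_idx = np.asarray(config.hub_rois, dtype=int)
    inter_idx = np.asarray(config.interaction_rois, dtype=int)

    subjects: list[SubjectTimeSeries] = []
    T = config.n_volumes
    for s in range(n):
        mult = loading_multiplier(
            config,
            is_case=bool(ptsd[s]),
            months=float(months[s]),
            symptom_index=float(index_centered[s]),
            symptom_loading=symptom_loading,
        )

        Ls = (L + config.loading_jitter
              * noise_rng.standard_normal(L.shape)) * mult[:, None]
        F = _ar1(noise_rng, (config.n_factors, T), config.factor_ar)
        noise = config.noise_sd * _ar1(
            noise_rng, (config.n_roi, T), config.ar_coefficient)
        motion = 0.5 * _ar1(noise_rng, (6, T), 0.95)
        wm = _ar1(noise_rng, (T,), 0.5)
        csf = _ar1(noise_rng, (T,), 0.5)

        motion_gain = 0.15 * noise_rng.standard_normal((config.n_roi, 6))
        wm_gain = 0.2 + 0.05 * noise_rng.standard_normal(config.n_roi)
        csf_gain = 0.2 + 0.05 * noise_rng.standard_normal(config.n_roi)

        data = (Ls @ F + noise + motion_gain @ motion
                + np.outer(wm_gain, wm) + np.outer(csf_gain, csf))
        subjects.append(
            SubjectTimeSeries(
                subject_id=subject_ids[s],
                data=data,
                motion=motion,
                wm=wm,
                csf=csf,
            )
        )
    return subjects, pheno


# ---------------------------------------------------------------------------
# descriptive statistics

CONTINUOUS_VARS = ["months_on_site", *scid_scales.SUBSCALES]
CATEGORICAL_VARS = ["mdd", "psychotropic", "opioid"]


def cohort_report(
    phenotypes: pd.DataFrame,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Group descriptives with Welch t (continuous) or chi-square p-values.

    One row per variable: per-group mean +/- SD or counts, the test
    statistic and p. Variables that are constant in both groups are
    skipped with a ``degenerate`` flag instead of a test.
    """
    continuous = CONTINUOUS_VARS if continuous is None else continuous
    categorical = CATEGORICAL_VARS if categorical is None else categorical
    groups = phenotypes.groupby("ptsd")
    sizes = groups.size()
    if len(sizes) < 2 or sizes.min() < 2:
        raise ValueError("need at least 2 subjects in each of two groups")
    case = phenotypes[phenotypes["ptsd"] == 1]
    ctrl = phenotypes[phenotypes["ptsd"] == 0]

    rows = []
    for var in continuous:
        a = case[var].dropna().to_numpy(dtype=float)
        b = ctrl[var].dropna().to_numpy(dtype=float)
        row = {
            "variable": var,
            "type": "continuous",
            "case_summary": f"{a.mean():.2f} +/- {a.std(ddof=1):.2f}",
            "control_summary": f"{b.mean():.2f} +/- {b.std(ddof=1):.2f}",
        }
        if a.std() == 0 and b.std() == 0:
            row.update(statistic=np.nan, p=np.nan, flag="degenerate")
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            row.update(statistic=float(t), p=float(p), flag="")
        rows.append(row)
    for var in categorical:
        tab = pd.crosstab(phenotypes["ptsd"], phenotypes[var])
        row = {
            "variable": var,
            "type": "categorical",
            "case_summary": _count_summary(case[var]),
            "control_summary": _count_summary(ctrl[var]),
        }
        if tab.shape[1] < 2:
            row.update(statistic=np.nan, p=np.nan, flag="degenerate")
        else:
            chi2, p, *_ = stats.chi2_contingency(tab)
            row.update(statistic=float(chi2), p=float(p), flag="")
        rows.append(row)
    return pd.DataFrame(rows)


def _count_summary(col: pd.Series) -> str:
    n = int(col.sum())
    return f"{n} ({100.0 * n / len(col):.0f}%)"


# ---------------------------------------------------------------------------
# on-disk layout

def write_cohort(subjects: list[SubjectTimeSeries], phenotypes: pd.DataFrame,
                 outdir: str | Path, config: CohortConfig | None = None
                 ) -> Path:
    """Write per-subject TSVs, the phenotype CSV and a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for sub in subjects:
        ts_path = outdir / f"{sub.subject_id}_timeseries.tsv"
        conf_path = outdir / f"{sub.subject_id}_confounds.tsv"
        pd.DataFrame(
            sub.data.T,
            columns=[f"roi_{i}" for i in range(sub.data.shape[0])],
        ).to_csv(ts_path, sep="\t", index=False)
        conf = pd.DataFrame(
            sub.motion.T, columns=[f"mot_{i + 1}" for i in range(6)])
        conf["wm"] = sub.wm
        conf["csf"] = sub.csf
        conf.to_csv(conf_path, sep="\t", index=False)
        entries.append(
            {
                "subject_id": sub.subject_id,
                "timeseries": ts_path.name,
                "confounds": conf_path.name,
            }
        )
    pheno_path = outdir / "phenotypes.csv"
    phenotypes.to_csv(pheno_path, index=False)
    manifest = {
        "phenotypes": pheno_path.name,
        "subjects": entries,
        "seed": None if config is None else config.seed,
        "config": None if config is None else asdict(config),
        "config_hash": None if config is None else config.hash(),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=list))
    return manifest_path


def read_cohort(outdir: str | Path
                ) -> tuple[list[SubjectTimeSeries], pd.DataFrame]:
    """Load a cohort written by :func:`write_cohort`."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    phenotypes = pd.read_csv(outdir / manifest["phenotypes"])
    subjects = []
    for entry in manifest["subjects"]:
        # round_trip parsing keeps the write/read cycle bit-identical
        data = pd.read_csv(outdir / entry["timeseries"], sep="\t",
                           float_precision="round_trip")
        conf = pd.read_csv(outdir / entry["confounds"], sep="\t",
                           float_precision="round_trip")
        subjects.append(
            SubjectTimeSeries(
                subject_id=entry["subject_id"],
                data=data.to_numpy(dtype=float).T,
                motion=conf[[f"mot_{i + 1}" for i in range(6)]]
                .to_numpy(dtype=float).T,
                wm=conf["wm"].to_numpy(dtype=float),
                csf=conf["csf"].to_numpy(dtype=float),
            )
        )
    return subjects, phenotypes
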