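"""Misannotation estimation: mismatch rates, consensus calls, and
per-study Gaussian-mixture clustering of sample sex scores.

The mixture fitter models each study's score distribution as one or two
unequal-variance Gaussians, optionally plus a uniform noise component on
[0, 1] covering scores in the unclassified band.  Variances are
regularized by a weak inverse-gamma prior governed by ``prior_scale`` (the
M-step adds prior_scale^2 of pseudo-variance), and model order is chosen
by BIC.  Two-component fits whose means are closer than
``min_separation`` are discarded before any flagging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

FEMALE = "female"
MALE = "male"
UNLABELED = "unlabeled"

MATCH = "match"
MISMATCH = "mismatch"
UNCLEAR = "unclear"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClusterConfig:
    prior_scale: float = 0.15
    posterior_cutoff: float = 0.95
    min_separation: float = 0.3
    noise_band: tuple[float, float] = (0.3, 0.7)
    noise_disable_frac: float = 1.0 / 3.0
    max_components: int = 2
    max_iter: int = 500
    tol: float = 1e-8
    n_restarts: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.posterior_cutoff < 1.0:
            raise ValueError("posterior_cutoff must be in (0, 1)")
        if not 0.0 <= self.min_separation <= 1.0:
            raise ValueError("min_separation must be in [0, 1]")


# ---------------------------------------------------------------------------
# Simple mismatch rates (procedure 1)
# ---------------------------------------------------------------------------

def simple_mismatch_rates(df: pd.DataFrame, categories: pd.DataFrame,
                          min_study_size: int = 10) -> dict:
    """Sample/study mismatch rates in large single- vs mixed-sex studies.

    ``df`` columns: sample_id, study_id, metadata_sex, expr_label.
    ``categories`` columns: study_id, category (from metadata labels).
    A mismatch is a sample with opposite metadata and expression sex;
    expression-unlabeled samples are excluded from the denominator.
    Returns per-stratum sample/study rates and a 2x2 chi-squared comparing
    sample mismatch counts between strata.
    """
    single = {"female-only", "male-only"}
    mixed = {"mixed", "mostly-female", "mostly-male"}
    cat_of = categories.set_index("study_id")["category"]
    sizes = df.groupby("study_id")["sample_id"].nunique()

    ev = df[df["metadata_sex"].isin([FEMALE, MALE]) &
            df["expr_label"].isin([FEMALE, MALE])].copy()
    ev["mismatch"] = ev["metadata_sex"] != ev["expr_label"]

    result: dict = {"strata": {}}
    counts = {}
    for name, cats in (("single", single), ("mixed", mixed)):
        studies = [s for s in sizes.index
                   if sizes[s] >= min_study_size and cat_of.get(s) in cats]
        sub = ev[ev["study_id"].isin(studies)]
        n = len(sub)
        n_mm = int(sub["mismatch"].sum())
        per_study = sub.groupby("study_id")["mismatch"].any() if n else pd.Series(dtype=bool)
        result["strata"][name] = {
            "n_samples": n,
            "n_mismatch": n_mm,
            "sample_rate": n_mm / n if n else float("nan"),
            "n_studies": len(studies),
            "study_rate": float(per_study.mean()) if len(per_study) else float("nan"),
        }
        counts[name] = (n_mm, n - n_mm)
    if all(sum(counts[k]) > 0 for k in counts):
        chi2, p = chi2_2x2(np.array([counts["single"], counts["mixed"]]))
        result["chi2"] = {"statistic": chi2, "p": p}
    return result


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, no continuity correction, 1 df.

    Identical margins (zero expected variation) return (0, 1).
    """
    table = np.asarray(table, float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if (expected == 0).any():
        return 0.0, 1.0
    stat = float(((table - expected) ** 2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Consensus across labelers (procedure 2)
# ---------------------------------------------------------------------------

def consensus_mismatch(meta_labels: pd.Series, method_labels: list[pd.Series]) -> pd.Series:
    """Conservative consensus: mismatch only if every voting method disagrees.

    Methods may abstain with "unlabeled".  Samples where no method voted, or
    whose metadata sex is not female/male, are "insufficient".
    """
    if len(method_labels) < 2:
        raise ValueError("need at least two methods for consensus")
    out = {}
    for sample in meta_labels.index:
        meta = meta_labels[sample]
        votes = [m[sample] for m in method_labels
                 if sample in m.index and m[sample] in (FEMALE, MALE)]
        if meta not in (FEMALE, MALE) or not votes:
            out[sample] = "insufficient"
        elif all(v != meta for v in votes):
            out[sample] = MISMATCH
        else:
            out[sample] = MATCH
    return pd.Series(out, name="consensus")


def baseline_cluster_labeler(y_matrix: pd.DataFrame) -> pd.Series:
    """Two-cluster baseline on mean Y-gene expression (stand-in labeler).

    Splits samples by 1-D two-means on the per-sample mean of Y genes; the
    higher-mean cluster is male.  Abstains (all "unlabeled") on < 4
    samples, constant input, or tied cluster means.
    """
    means = y_matrix.mean(axis=1).to_numpy(float)
    abstain = pd.Series(UNLABELED, index=y_matrix.index, name="label")
    if len(means) < 4 or np.ptp(means) == 0:
        return abstain
    c = np.array([means.min(), means.max()], float)
    assign = np.zeros(len(means), int)
    for _ in range(100):
        new_assign = (np.abs(means - c[0]) > np.abs(means - c[1])).astype(int)
        for k in (0, 1):
            if (new_assign == k).any():
                c[k] = means[new_assign == k].mean()
        if (new_assign == assign).all():
            break
        assign = new_assign
    if c[0] == c[1] or (assign == assign[0]).all():
        return abstain
    male_cluster = int(np.argmax(c))
    labels = np.where(assign == male_cluster, MALE, FEMALE)
    return pd.Series(labels, index=y_matrix.index, name="label")


# ---------------------------------------------------------------------------
# Gaussian mixture clustering (procedure 3)
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """Raw EM result for one candidate model."""

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray  # gaussian weights; noise weight separate
    noise_weight: float
    has_noise: bool
    loglik: float
    loglik_trace: list[float] = field(default_factory=list, repr=False)
    responsibilities: np.ndarray | None = field(default=None, repr=False)
    noise_resp: np.ndarray | None = field(default=None, repr=False)
    converged: bool = True

    @property
    def n_components(self) -> int:
        return len(self.means)

    def n_params(self) -> int:
        k = self.n_components
        n_weights = k + (1 if self.has_noise else 0) - 1
        return 2 * k + n_weights

    def bic(self, n: int) -> float:
        """k_params * ln(n) - 2 * ln(L)."""
        return self.n_params() * math.log(n) - 2.0 * self.loglik


@dataclass
class StudyClusterFit:
    study_id: str
    n_components: int
    fit: MixtureFit
    samples: pd.Index
    discarded: bool
    reason: str | None  # single_component | low_separation | no_convergence
    bic_by_model: dict[int, float]


def _em(x: np.ndarray, means0: np.ndarray, cfg: ClusterConfig,
        has_noise: bool, init_noise_resp: np.ndarray | None) -> MixtureFit:
    """MAP EM for a k-Gaussian (+ optional uniform-noise) mixture on [0, 1].

    The inverse-gamma variance prior enters the M-step as
    var = (S_k + 2 * prior_scale^2) / (n_k + 3); the trace records the
    penalized objective, which EM makes non-decreasing.
    """
    n, k = len(x), len(means0)
    b = cfg.prior_scale ** 2 / 2.0  # IG(a=1/2, b) => mode form below
    means = means0.astype(float).copy()
    variances = np.full(k, max(np.var(x), 1e-4))
    if has_noise and init_noise_resp is not None and init_noise_resp.sum() > 0:
        resp = np.zeros((n, k))
        nearest = np.argmin(np.abs(x[:, None] - means[None, :]), axis=1)
        for i in range(n):
            if init_noise_resp[i] < 1.0:
                resp[i, nearest[i]] = 1.0 - init_noise_resp[i]
        noise_resp = init_noise_resp.astype(float).copy()
    else:
        nearest = np.argmin(np.abs(x[:, None] - means[None, :]), axis=1)
        resp = np.eye(k)[nearest].astype(float)
        noise_resp = np.zeros(n)

    weights = np.full(k, 1.0 / (k + int(has_noise)))
    noise_weight = float(has_noise) / (k + int(has_noise))

    def penalized_objective(ll: float) -> float:
        pen = sum(-2.0 * b / v - 1.5 * math.log(v) for v in variances)
        return ll + pen

    trace: list[float] = []
    prev = -np.inf
    converged = False
    for _ in range(cfg.max_iter):
        # M-step
        nk = resp.sum(axis=0)
        n_noise = noise_resp.sum()
        total = nk.sum() + n_noise
        weights = nk / total
        noise_weight = n_noise / total
        for j in range(k):
            if nk[j] > 1e-12:
                means[j] = (resp[:, j] * x).sum() / nk[j]
            s = (resp[:, j] * (x - means[j]) ** 2).sum()
            variances[j] = (s + 4.0 * b) / (nk[j] + 3.0)
        # E-step
        dens = np.zeros((n, k))
        for j in range(k):
            dens[:, j] = weights[j] * stats.norm.pdf(x, means[j], math.sqrt(variances[j]))
        noise_dens = noise_weight * np.where((x >= 0) & (x <= 1), 1.0, 0.0) if has_noise else np.zeros(n)
        norm = dens.sum(axis=1) + noise_dens
        norm = np.maximum(norm, 1e-300)
        resp = dens / norm[:, None]
        noise_resp = noise_dens / norm
        ll = float(np.log(norm).sum())
        obj = penalized_objective(ll)
        trace.append(obj)
        if obj - prev < cfg.tol and len(trace) > 1:
            converged = True
            break
        prev = obj
    return MixtureFit(
        means=means, variances=variances, weights=weights,
        noise_weight=noise_weight, has_noise=has_noise, loglik=ll,
        loglik_trace=trace, responsibilities=resp, noise_resp=noise_resp,
        converged=converged,
    )


def _restart_means(x: np.ndarray, k: int, cfg: ClusterConfig) -> list[np.ndarray]:
    if k == 1:
        return [np.array([x.mean()])]
    pairs = [(0.1, 0.9), (0.25, 0.75), (0.05, 0.95), (0.35, 0.65), (0.0, 1.0)]
    return [np.quantile(x, p) for p in pairs[: cfg.n_restarts]]


def fit_study_mixture(scores: pd.Series, config: ClusterConfig = ClusterConfig(),
                      study_id: str = "") -> StudyClusterFit:
    """Fit 1- and 2-component score mixtures for one study and select by BIC.

    A uniform noise component is included iff any score falls in the
    unclassified band and the in-band fraction is at most
    ``noise_disable_frac``; its responsibilities are initialized to exactly
    the in-band samples.  One-component selections and low-separation
    two-component fits are discarded (never flagged).
    """
    x = np.asarray(scores, float)
    if len(x) < 4:
        raise ValueError("need >= 4 scored samples per study")
    lo, hi = config.noise_band
    in_band = (x > lo) & (x < hi)
    has_noise = bool(in_band.any()) and in_band.mean() <= config.noise_disable_frac
    init_noise = in_band.astype(float) if has_noise else None

    fits: dict[int, MixtureFit] = {}
    for k in range(1, config.max_components + 1):
        best = None
        for means0 in _restart_means(x, k, config):
            fit = _em(x, np.asarray(means0), config, has_noise, init_noise)
            if best is None or fit.loglik_trace[-1] > best.loglik_trace[-1]:
                best = fit
        fits[k] = best
    bics = {k: f.bic(len(x)) for k, f in fits.items()}
    k_star = min(bics, key=lambda k: (bics[k], k))
    fit = fits[k_star]

    discarded, reason = False, None
    if not fit.converged:
        discarded, reason = True, "no_convergence"
    elif k_star == 1:
        discarded, reason = True, "single_component"
    elif abs(fit.means[1] - fit.means[0]) < config.min_separation:
        discarded, reason = True, "low_separation"
    return StudyClusterFit(
        study_id=study_id, n_components=k_star, fit=fit,
        samples=scores.index, discarded=discarded, reason=reason,
        bic_by_model=bics,
    )


def flag_swaps(fit: StudyClusterFit, meta_sex: pd.Series,
               config: ClusterConfig = ClusterConfig()) -> pd.DataFrame:
    """Per-sample match/mismatch/unclear/unclassified flags for one study.

    Clusters are oriented by mean (higher mean = male).  A sample whose
    posterior for a cluster exceeds the cutoff is a match or mismatch by
    comparison with its metadata sex; noise-captured samples are
    unclassified; everything else is unclear.
    """
    if fit.discarded:
        raise ValueError(f"study {fit.study_id} was discarded ({fit.reason})")
    m = fit.fit
    order = np.argsort(m.means)  # order[0]=female cluster, order[1]=male
    sex_of_cluster = {int(order[0]): FEMALE, int(order[1]): MALE}
    rows = []
    for i, sample in enumerate(fit.samples):
        resp = m.responsibilities[i]
        noise = m.noise_resp[i] if m.noise_resp is not None else 0.0
        j = int(np.argmax(resp))
        meta = meta_sex.get(sample, UNLABELED)
        if noise > resp[j]:
            flag, post, comp = UNCLASSIFIED, float(noise), "noise"
        elif resp[j] > config.posterior_cutoff and meta in (FEMALE, MALE):
            flag = MATCH if sex_of_cluster[j] == meta else MISMATCH
            post, comp = float(resp[j]), sex_of_cluster[j]
        else:
            flag, post, comp = UNCLEAR, float(resp[j]), sex_of_cluster[j]
        rows.append({"sample_id": sample, "study_id": fit.study_id,
                     "flag": flag, "posterior": post, "component": comp})
    return pd.DataFrame(rows)


def flag_all_studies(scores: pd.DataFrame, config: ClusterConfig = ClusterConfig(),
                     min_samples: int = 4) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the mixture fitter over every study in a score table.

    ``scores`` columns: sample_id, study_id, score, metadata_sex.
    Returns (per-sample flags, per-study fit summary).
    """
    flags, studies = [], []
    for study_id, g in scores.groupby("study_id", sort=True):
        if len(g) < min_samples:
            studies.append({"study_id": study_id, "n_samples": len(g),
                            "n_components": 0, "mean_low": float("nan"),
                            "mean_high": float("nan"), "discarded": True,
                            "reason": "too_few_samples"})
            continue
        s = pd.Series(g["score"].to_numpy(), index=g["sample_id"].to_numpy())
        fit = fit_study_mixture(s, config, study_id=study_id)
        means = np.sort(fit.fit.means)
        studies.append({"study_id": study_id, "n_samples": len(g),
                        "n_components": fit.n_components,
                        "mean_low": float(means[0]), "mean_high": float(means[-1]),
                        "discarded": fit.discarded, "reason": fit.reason or ""})
        if not fit.discarded:
            meta = pd.Series(g["metadata_sex"].to_numpy(), index=g["sample_id"].to_numpy())
            flags.append(flag_swaps(fit, meta, config))
    flag_df = (pd.concat(flags, ignore_index=True) if flags
               else pd.DataFrame(columns=["sample_id", "study_id", "flag",
                                          "posterior", "component"]))
    return flag_df, pd.DataFrame(studies)
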