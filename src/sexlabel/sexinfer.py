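"""Penalized logistic sex inference with study-stratified nested CV.

The model is an elastic-net logistic regression over X/Y-chromosome genes
producing P(male) "sample sex scores" (female coded 0, male coded 1).
Hyperparameters (alpha, lambda) are selected by nested cross-validation:
outer folds partition study groups; per outer fold and alpha, lambda-1se is
chosen by inner CV (binomial deviance, the cv.glmnet default error) on the
remaining folds; the final alpha minimizes the median validation
classification error (ties broken toward the sparser, larger alpha) and
the final lambda is the median of that alpha's per-fold choices — the
percentile rule at the 50th percentile, extended to both hyperparameters.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FEMALE = "female"
MALE = "male"
UNLABELED = "unlabeled"

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))


# ---------------------------------------------------------------------------
# Study groups
# ---------------------------------------------------------------------------

@dataclass
class StudyGroupMap:
    """study_id -> group_id, with removed (overly shared) studies tracked."""

    group_of: dict[str, str]
    removed_studies: set[str]

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for study, group in self.group_of.items():
            out.setdefault(group, []).append(study)
        return out


def build_study_groups(membership: pd.DataFrame, max_shared: int = 5) -> StudyGroupMap:
    """Group studies into connected components of the shared-sample graph.

    Studies that share >= 1 sample with more than ``max_shared`` other
    studies are removed first; the remaining studies are grouped so any two
    studies sharing a sample land in the same group.
    """
    if membership.empty:
        raise ValueError("empty study membership")
    studies_of_sample: dict[str, set[str]] = {}
    for sample, study in zip(membership["sample_id"], membership["study_id"]):
        studies_of_sample.setdefault(sample, set()).add(study)

    neighbours: dict[str, set[str]] = {}
    for studies in studies_of_sample.values():
        for s in studies:
            neighbours.setdefault(s, set()).update(studies - {s})
    removed = {s for s, nb in neighbours.items() if len(nb) > max_shared}

    parent: dict[str, str] = {s: s for s in neighbours if s not in removed}

    def find(s: str) -> str:
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    for studies in studies_of_sample.values():
        kept = sorted(studies - removed)
        for a, b in zip(kept, kept[1:]):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    roots = sorted({find(s) for s in parent})
    group_id = {root: f"G{i:05d}" for i, root in enumerate(roots)}
    return StudyGroupMap(
        group_of={s: group_id[find(s)] for s in sorted(parent)},
        removed_studies=removed,
    )


# ---------------------------------------------------------------------------
# Train / test construction
# ---------------------------------------------------------------------------

def construct_train_test(
    samples: pd.DataFrame,
    groups: StudyGroupMap,
    max_per_study: int = 5,
    test_frac: float = 0.2,
    balance_band: tuple[float, float] = (0.45, 0.55),
    seed: int = 0,
    max_tries: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split labeled samples into train/test sets stratified by study group.

    ``samples`` columns: sample_id, study_id, sex (female/male).  At most
    ``max_per_study`` samples are drawn per study; study groups never span
    both splits; both splits must have a male fraction inside
    ``balance_band`` (randomized group assignment retried up to
    ``max_tries`` times).
    """
    rng = np.random.default_rng(seed)
    df = samples[samples["sex"].isin([FEMALE, MALE])].copy()
    df = df[df["study_id"].isin(groups.group_of)]
    if df.empty:
        raise ValueError("no labeled samples in grouped studies")

    picked = []
    for _, g in df.sort_values("sample_id").groupby("study_id", sort=True):
        if len(g) <= max_per_study:
            picked.append(g)
            continue
        # draw alternately from each sex so the pooled set stays balanced
        females = g[g["sex"] == FEMALE].sample(frac=1.0, random_state=rng.integers(2**31))
        males = g[g["sex"] == MALE].sample(frac=1.0, random_state=rng.integers(2**31))
        if len(females) != len(males):
            female_first = len(females) > len(males)
        else:
            female_first = bool(rng.integers(2))
        take, fi, mi = [], 0, 0
        for t in range(max_per_study):
            pick_female = (t % 2 == (0 if female_first else 1) and fi < len(females)) \
                or mi >= len(males)
            if pick_female and fi < len(females):
                take.append(females.iloc[fi])
                fi += 1
            elif mi < len(males):
                take.append(males.iloc[mi])
                mi += 1
        picked.append(pd.DataFrame(take))
    df = pd.concat(picked, ignore_index=True)
    df["group"] = df["study_id"].map(groups.group_of)

    per_group = df.groupby("group").agg(
        n=("sample_id", "size"), n_male=("sex", lambda s: int((s == MALE).sum()))
    )
    group_ids = np.array(sorted(per_group.index))
    n_total = int(per_group["n"].sum())
    target_test = test_frac * n_total

    lo, hi = balance_band
    n_arr = per_group.loc[group_ids, "n"].to_numpy()
    m_arr = per_group.loc[group_ids, "n_male"].to_numpy()

    def violation(in_test: np.ndarray) -> float:
        nt, mt = n_arr[in_test].sum(), m_arr[in_test].sum()
        nr, mr = n_arr[~in_test].sum(), m_arr[~in_test].sum()
        if nt == 0 or nr == 0:
            return np.inf
        ft, fr = mt / nt, mr / nr
        band = (max(0.0, lo - ft) + max(0.0, ft - hi)
                + max(0.0, lo - fr) + max(0.0, fr - hi))
        return band + 0.1 * abs(nt - target_test) / n_total

    def in_band(in_test: np.ndarray) -> bool:
        nt, mt = n_arr[in_test].sum(), m_arr[in_test].sum()
        nr, mr = n_arr[~in_test].sum(), m_arr[~in_test].sum()
        return (nt > 0 and nr > 0
                and lo <= mt / nt <= hi and lo <= mr / nr <= hi)

    def trim_to_band(split: pd.DataFrame) -> pd.DataFrame:
        """Randomly drop majority-sex samples until the split is in band.

        The reference procedure *selects* balanced train/test sets rather
        than exhaustively partitioning all labeled samples, so trimming the
        majority sex is the faithful repair.
        """
        n_m = int((split["sex"] == MALE).sum())
        n_f = len(split) - n_m
        if n_m == 0 or n_f == 0:
            raise ValueError("cannot balance a single-sex split; too few "
                             f"labeled samples ({n_m} male, {n_f} female)")
        while not lo <= n_m / (n_m + n_f) <= hi:
            majority = MALE if n_m / (n_m + n_f) > hi else FEMALE
            pool = split.index[split["sex"] == majority].to_numpy()
            split = split.drop(rng.choice(pool))
            n_m = int((split["sex"] == MALE).sum())
            n_f = len(split) - n_m
        return split.reset_index(drop=True)

    best_assign, best_score = None, np.inf
    n_restarts = max(1, max_tries // 100)
    for _ in range(n_restarts):
        order = rng.permutation(len(group_ids))
        in_test = np.zeros(len(group_ids), bool)
        size = 0
        for gi in order:
            if size >= target_test:
                break
            in_test[gi] = True
            size += int(n_arr[gi])
        score = violation(in_test)
        # hill-climb: toggle single groups to repair balance and size
        for _ in range(100 * len(group_ids)):
            if in_band(in_test):
                break
            gi = int(rng.integers(len(group_ids)))
            in_test[gi] = ~in_test[gi]
            cand = violation(in_test)
            if cand < score:
                score = cand
            else:
                in_test[gi] = ~in_test[gi]
        if score < best_score and in_test.any() and not in_test.all():
            best_assign, best_score = in_test.copy(), score
        if in_band(in_test):
            break
    if best_assign is None:
        raise ValueError(
            f"could not build a split: {n_total} labeled samples, "
            f"{len(group_ids)} groups, band {balance_band}")
    test_groups = set(group_ids[best_assign])
    test = trim_to_band(df[df["group"].isin(test_groups)])
    train = trim_to_band(df[~df["group"].isin(test_groups)])
    return train, test


# ---------------------------------------------------------------------------
# Elastic-net fitting (glmnet-style parameterization)
# ---------------------------------------------------------------------------

def enet_logistic(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    coef0: np.ndarray | None = None,
    intercept0: float = 0.0,
    max_outer: int = 50,
    max_inner: int = 200,
    tol: float = 1e-8,
) -> tuple[np.ndarray, float]:
    """Elastic-net logistic regression by IRLS + coordinate descent.

    Minimizes mean log-loss + lam * (alpha*||b||_1 + (1-alpha)/2*||b||_2^2)
    (the glmnet parameterization; the intercept is unpenalized).  The inner
    weighted least-squares problem is solved with covariance (Gram) updates
    so each coordinate pass costs O(p^2) regardless of n.  ``X`` is assumed
    standardized; warm starts via ``coef0``/``intercept0``.
    """
    n, p = X.shape
    y = np.asarray(y, float)
    beta = np.zeros(p) if coef0 is None else coef0.astype(float).copy()
    b0 = float(intercept0)
    l1 = lam * alpha
    l2 = lam * (1.0 - alpha)

    for _ in range(max_outer):
        eta = b0 + X @ beta
        prob = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(prob * (1.0 - prob), 1e-5, None)
        z = eta + (y - prob) / w
        Xw = X * w[:, None]
        A = (Xw.T @ X) / n            # (1/n) X' W X
        c = (Xw.T @ z) / n            # (1/n) X' W z
        xw_mean = Xw.mean(axis=0)
        zw_mean = float((w * z).mean())
        sw = float(w.mean())
        diag = np.diag(A).copy()
        denom = diag + l2
        beta_old = beta.copy()
        b0_old = b0
        for _ in range(max_inner):
            delta = 0.0
            new_b0 = (zw_mean - xw_mean @ beta) / sw
            delta = max(delta, abs(new_b0 - b0))
            b0 = new_b0
            for j in range(p):
                rho = c[j] - b0 * xw_mean[j] - A[j] @ beta + diag[j] * beta[j]
                new = math.copysign(max(abs(rho) - l1, 0.0), rho) / denom[j]
                delta = max(delta, abs(new - beta[j]))
                beta[j] = new
            if delta < tol:
                break
        if max(float(np.max(np.abs(beta - beta_old))), abs(b0 - b0_old)) < 1e-6:
            break
    return beta, b0


class _EnetModel:
    """Minimal fitted-model wrapper used inside the CV loops."""

    __slots__ = ("coef_", "intercept_")

    def __init__(self, coef: np.ndarray, intercept: float) -> None:
        self.coef_ = coef
        self.intercept_ = intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.intercept_ + X @ self.coef_ > 0).astype(int)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(self.intercept_ + X @ self.coef_)))


def binomial_deviance(prob: np.ndarray, y: np.ndarray) -> float:
    """Mean binomial deviance (the cv.glmnet default CV error for logistic)."""
    p = np.clip(prob, 1e-10, 1.0 - 1e-10)
    y = np.asarray(y, float)
    return float(-2.0 * np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _fit_enet(X: np.ndarray, y: np.ndarray, alpha: float, lam: float,
              warm: _EnetModel | None = None) -> _EnetModel:
    coef0 = warm.coef_ if warm is not None else None
    b00 = warm.intercept_ if warm is not None else 0.0
    beta, b0 = enet_logistic(X, y, alpha, lam, coef0=coef0, intercept0=b00)
    return _EnetModel(beta, b0)

def lambda_path(X: np.ndarray, y: np.ndarray, alpha: float,
                n_lambda: int = 20, lambda_min_ratio: float = 1e-3) -> np.ndarray:
    """Decreasing log-spaced lambda grid from the glmnet-style lambda_max."""
    ybar = y.mean()
    grad = X.T @ (y - ybar) / len(y)
    lam_max = np.abs(grad).max() / max(alpha, 1e-3)
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def make_outer_folds(df: pd.DataFrame, n_folds: int = 6) -> np.ndarray:
    """Greedy balanced partition of study groups into outer folds.

    Groups (by sample count descending, group id as tie-break) are assigned
    to the currently smallest fold.  Deterministic.  Returns a fold index
    per row of ``df``.
    """
    sizes = df.groupby("group").size()
    order = sorted(sizes.index, key=lambda g: (-sizes[g], g))
    fold_of_group: dict[str, int] = {}
    fold_sizes = np.zeros(n_folds, int)
    for group in order:
        f = int(np.argmin(fold_sizes))
        fold_of_group[group] = f
        fold_sizes[f] += sizes[group]
    return df["group"].map(fold_of_group).to_numpy()


@dataclass
class SexModel:
    """Fitted linear scorer over X/Y genes producing P(male)."""

    genes: list[str]
    coef: np.ndarray  # on the standardized scale
    intercept: float
    alpha: float
    lam: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    threshold_high: float = 0.7
    seed: int = 0
    training_manifest: dict = field(default_factory=dict)
    cv_table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def threshold_low(self) -> float:
        return 1.0 - self.threshold_high

    def score(self, matrix: pd.DataFrame) -> pd.Series:
        """P(male) for each sample; missing model genes are imputed with the
        training mean (standardized value 0)."""
        present = [g for g in self.genes if g in matrix.columns]
        if not present:
            raise ValueError("no overlap between model genes and matrix columns")
        Z = np.zeros((len(matrix), len(self.genes)))
        for j, g in enumerate(self.genes):
            if g in matrix.columns:
                sd = self.feature_sds[j]
                if sd > 0:
                    Z[:, j] = (matrix[g].to_numpy(float) - self.feature_means[j]) / sd
        eta = self.intercept + Z @ self.coef
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=matrix.index, name="score")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": self.genes,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "alpha": self.alpha,
            "lambda": self.lam,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "threshold_high": self.threshold_high,
            "seed": self.seed,
            "training_manifest": self.training_manifest,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SexModel":
        d = json.loads(Path(path).read_text())
        return cls(
            genes=d["genes"], coef=np.asarray(d["coef"]), intercept=d["intercept"],
            alpha=d["alpha"], lam=d["lambda"],
            feature_means=np.asarray(d["feature_means"]),
            feature_sds=np.asarray(d["feature_sds"]),
            threshold_high=d.get("threshold_high", 0.7), seed=d.get("seed", 0),
            training_manifest=d.get("training_manifest", {}),
        )


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds_safe = np.where(sds > 0, sds, 1.0)
    return (X - means) / sds_safe, means, sds


def lambda_1se(mean_err: np.ndarray, se_err: np.ndarray, lambdas: np.ndarray) -> float:
    """Largest lambda whose mean CV error is within one SE of the minimum."""
    i_min = int(np.argmin(mean_err))
    bound = mean_err[i_min] + se_err[i_min]
    ok = np.nonzero(mean_err <= bound)[0]
    return float(lambdas[ok[0]])  # lambdas are decreasing: first = largest


def nested_cv_fit(
    X: pd.DataFrame,
    y: np.ndarray,
    group_per_sample: np.ndarray,
    feature_table: pd.DataFrame | None = None,
    n_folds: int = 6,
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    n_lambda: int = 20,
    seed: int = 0,
    threshold_high: float = 0.7,
) -> SexModel:
    """Fit the sex model with study-group-stratified nested CV.

    ``X``: training expression restricted to X/Y genes (samples x genes).
    ``y``: 0/1 labels (female=0, male=1).  ``group_per_sample``: study-group
    id per row.  ``feature_table`` (optional, gene_id/chromosome/xi_status)
    is used only to verify no autosomal genes slipped in.
    """
    if feature_table is not None:
        chrom = feature_table.set_index("gene_id")["chromosome"]
        bad = [g for g in X.columns if chrom.get(g, "autosome") not in ("X", "Y")]
        if bad:
            raise ValueError(f"autosomal or unannotated genes in feature set: {bad[:5]}")
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    Xv = X.to_numpy(float)
    if not np.all(np.isfinite(Xv)):
        raise ValueError("non-finite feature values")
    Z, means, sds = _standardize(Xv)

    folds_df = pd.DataFrame({"group": group_per_sample})
    fold_idx = make_outer_folds(folds_df, n_folds)
    for f in range(n_folds):
        if len(np.unique(y[fold_idx == f])) < 2:
            raise ValueError(f"outer fold {f} does not contain both classes")

    records = []
    for alpha in alpha_grid:
        lambdas = lambda_path(Z, y, alpha, n_lambda=n_lambda)
        for f in range(n_folds):
            outer_mask = fold_idx == f
            inner_folds = [g for g in range(n_folds) if g != f]
            # inner CV: each remaining fold in turn is the inner validation set
            errs = np.zeros((len(inner_folds), len(lambdas)))
            for vi, v in enumerate(inner_folds):
                tr = ~outer_mask & (fold_idx != v)
                va = fold_idx == v
                est = None
                for li, lam in enumerate(lambdas):
                    est = _fit_enet(Z[tr], y[tr], alpha, lam, warm=est)
                    errs[vi, li] = binomial_deviance(est.predict_proba(Z[va]), y[va])
            mean_err = errs.mean(axis=0)
            se_err = errs.std(axis=0, ddof=1) / np.sqrt(len(inner_folds))
            lam_f = lambda_1se(mean_err, se_err, lambdas)
            est = _fit_enet(Z[~outer_mask], y[~outer_mask], alpha, lam_f)
            val_err = float(np.mean(est.predict(Z[outer_mask]) != y[outer_mask]))
            records.append({"alpha": alpha, "fold": f, "lambda_1se": lam_f,
                            "val_error": val_err})
    cv = pd.DataFrame(records)
    summary = cv.groupby("alpha").agg(
        median_error=("val_error", "median"), median_lambda=("lambda_1se", "median")
    ).reset_index()
    best_err = summary["median_error"].min()
    # tie-break toward the largest alpha (sparsest model)
    best = summary[summary["median_error"] <= best_err + 1e-12].sort_values("alpha").iloc[-1]
    alpha_star, lam_star = float(best["alpha"]), float(best["median_lambda"])

    final = _fit_enet(Z, y, alpha_star, lam_star)
    manifest = {
        "n_samples": int(len(y)),
        "n_male": int(y.sum()),
        "groups_hash": hashlib.sha256(
            ",".join(sorted(map(str, set(group_per_sample)))).encode()).hexdigest()[:16],
        "samples_hash": hashlib.sha256(
            ",".join(map(str, X.index)).encode()).hexdigest()[:16],
        "seed": int(seed),
    }
    return SexModel(
        genes=list(X.columns),
        coef=final.coef_.copy(),
        intercept=float(final.intercept_),
        alpha=alpha_star,
        lam=lam_star,
        feature_means=means,
        feature_sds=sds,
        threshold_high=threshold_high,
        seed=seed,
        training_manifest=manifest,
        cv_table=cv,
    )


# ---------------------------------------------------------------------------
# Scoring, labeling, QC
# ---------------------------------------------------------------------------

def predict_scores(model: SexModel, matrix: pd.DataFrame) -> pd.DataFrame:
    """Score every sample and attach threshold labels."""
    scores = model.score(matrix)
    out = pd.DataFrame({"sample_id": matrix.index, "score": scores.to_numpy()})
    out["label"] = assign_labels(out["score"], model.threshold_high)
    return out


def assign_labels(scores: pd.Series | np.ndarray, threshold_high: float = 0.7) -> pd.Series:
    """score >= threshold -> male; score <= 1-threshold -> female; else unlabeled.

    The unclassified band is the open interval, so boundary scores get a
    sex label.
    """
    s = pd.Series(np.asarray(scores, float))
    labels = np.full(len(s), UNLABELED, object)
    labels[s >= threshold_high] = MALE
    labels[s <= 1.0 - threshold_high] = FEMALE
    return pd.Series(labels, index=s.index, name="label")


def threshold_sweep(scores: pd.DataFrame,
                    grid: np.ndarray | None = None) -> pd.DataFrame:
    """Concordance vs. coverage across a threshold grid.

    ``scores`` columns: score, metadata_sex (female/male).  Concordance is
    computed only over samples that receive a label at each threshold.
    """
    if grid is None:
        grid = np.round(np.arange(0.5, 0.995, 0.01), 2)
    df = scores[scores["metadata_sex"].isin([FEMALE, MALE])].reset_index(drop=True)
    if df.empty:
        raise ValueError("no samples with metadata sex labels")
    rows = []
    for t in grid:
        labels = assign_labels(df["score"], t)
        labeled = labels != UNLABELED
        n_lab = int(labeled.sum())
        conc = float((labels[labeled].to_numpy() ==
                      df.loc[labeled.to_numpy(), "metadata_sex"].to_numpy()).mean()) if n_lab else float("nan")
        rows.append({"threshold": float(t), "concordance": conc,
                     "fraction_labeled": n_lab / len(df)})
    return pd.DataFrame(rows)


def platform_qc(scores: pd.DataFrame, floor: float = 0.70,
                min_n: int = 20) -> tuple[pd.DataFrame, set[str]]:
    """Per-platform concordance with metadata; platforms below the floor are excluded.

    ``scores`` columns: label, metadata_sex, platform.  Platforms with fewer
    than ``min_n`` evaluable (metadata-labeled and expression-labeled)
    samples are flagged insufficient rather than excluded.
    """
    df = scores[scores["metadata_sex"].isin([FEMALE, MALE]) &
                scores["label"].isin([FEMALE, MALE])]
    rows = []
    excluded: set[str] = set()
    for platform in sorted(scores["platform"].unique()):
        sub = df[df["platform"] == platform]
        n = len(sub)
        if n < min_n:
            rows.append({"platform": platform, "n_evaluable": n,
                         "concordance": float("nan"), "status": "insufficient"})
            continue
        conc = float((sub["label"] == sub["metadata_sex"]).mean())
        status = "excluded" if conc < floor else "ok"
        if status == "excluded":
            excluded.add(platform)
        rows.append({"platform": platform, "n_evaluable": n,
                     "concordance": conc, "status": status})
    return pd.DataFrame(rows), excluded
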