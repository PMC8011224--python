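"""Sex-breakdown summaries, cell-line concordance, and ATC enrichment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mislabel import chi2_2x2

FEMALE = "female"
MALE = "male"
UNLABELED = "unlabeled"

SINGLE_SEX = {"female-only", "male-only"}
MIXED_SEX = {"mixed", "mostly-female", "mostly-male"}


@dataclass(frozen=True)
class EnrichmentConfig:
    min_class_count: int = 5
    n_tests: int | None = 48  # None -> use the number of tests actually run
    alpha: float = 0.05


def sex_breakdown(labels: pd.DataFrame, strata: list[str] | None = None) -> pd.DataFrame:
    """Per-stratum female/male/unlabeled proportions at the sample level.

    ``labels`` columns: label plus any strata columns.  Empty strata are
    omitted; each row normalizes to 1.
    """
    strata = strata or []
    if strata:
        grouped = labels.groupby(strata, sort=True)
    else:
        grouped = [(("all",), labels)]
    rows = []
    for key, g in grouped:
        if len(g) == 0:
            continue
        key = key if isinstance(key, tuple) else (key,)
        counts = g["label"].value_counts()
        n = len(g)
        row = dict(zip(strata or ["stratum"], key))
        row.update({
            "n": n,
            "frac_female": counts.get(FEMALE, 0) / n,
            "frac_male": counts.get(MALE, 0) / n,
            "frac_unlabeled": counts.get(UNLABELED, 0) / n,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def study_category_breakdown(categories: pd.DataFrame) -> pd.DataFrame:
    """Proportion of studies per category."""
    counts = categories["category"].value_counts()
    n = len(categories)
    return pd.DataFrame(
        [{"category": c, "n": int(counts.get(c, 0)), "fraction": counts.get(c, 0) / n}
         for c in sorted(counts.index)]
    )


def cell_line_concordance(cellmap: pd.DataFrame,
                          min_studies: int = 5,
                          min_samples_per_study: int = 3) -> tuple[dict, pd.DataFrame]:
    """Donor-sex vs inferred-sex switch rates and per-line profiles.

    ``cellmap`` columns: sample_id, study_id, accession, donor_sex,
    inferred_label, score.  Switch rates use samples with a known donor sex
    and an inferred female/male label; unknown-donor-sex samples are
    reported separately.  Per-line profiles are restricted to lines with at
    least ``min_studies`` studies of ``min_samples_per_study``+ samples.
    """
    known = cellmap[cellmap["donor_sex"].isin([FEMALE, MALE])]
    rates = {"n_unknown_donor_sex": int(len(cellmap) - len(known))}
    for donor, other in ((MALE, FEMALE), (FEMALE, MALE)):
        sub = known[(known["donor_sex"] == donor) &
                    known["inferred_label"].isin([FEMALE, MALE])]
        n = len(sub)
        rates[f"{donor}_to_{other}"] = {
            "n": n,
            "rate": float((sub["inferred_label"] == other).mean()) if n else float("nan"),
        }

    profiles = []
    for acc, g in known.groupby("accession", sort=True):
        study_sizes = g.groupby("study_id").size()
        big = study_sizes[study_sizes >= min_samples_per_study]
        if len(big) < min_studies:
            continue
        gg = g[g["study_id"].isin(big.index)]
        n = len(gg)
        profiles.append({
            "accession": acc,
            "donor_sex": gg["donor_sex"].iloc[0],
            "n_studies": len(big),
            "n_samples": n,
            "frac_male": float((gg["inferred_label"] == MALE).mean()),
            "frac_female": float((gg["inferred_label"] == FEMALE).mean()),
            "frac_unlabeled": float((gg["inferred_label"] == UNLABELED).mean()),
            "median_score": float(gg["score"].median()),
        })
    return rates, pd.DataFrame(profiles)


def score_cnv_correlation(median_scores: pd.Series,
                          cnv_medians: pd.Series) -> tuple[float, float]:
    """Spearman correlation of per-line median scores vs copy-number medians."""
    common = median_scores.index.intersection(cnv_medians.index)
    if len(common) < 3:
        raise ValueError("need >= 3 cell lines with both score and CNV medians")
    rho, p = stats.spearmanr(median_scores[common], cnv_medians[common])
    return float(rho), float(p)


def atc_enrichment(study_classes: pd.DataFrame,
                   config: EnrichmentConfig = EnrichmentConfig()) -> pd.DataFrame:
    """Per-ATC-class chi-squared enrichment of study sex categories.

    ``study_classes`` columns: study_id, atc_class, category (one row per
    study-class pair; a study appears once per class it maps to).  For each
    class two 2x2 tests against all other classes are run: male-only vs
    female-only, and single- vs mixed-sex.  A class-test is dropped when any
    of its four in-class/out-of-class counts is below ``min_class_count``;
    significance uses p < alpha / n_tests.
    """
    df = study_classes.copy()
    df["mf"] = df["category"].map(
        lambda c: "male-only" if c == "male-only"
        else ("female-only" if c == "female-only" else None))
    df["sm"] = df["category"].map(
        lambda c: "single" if c in SINGLE_SEX else ("mixed" if c in MIXED_SEX else None))

    rows = []
    for test, col, levels in (("male_vs_female", "mf", ("male-only", "female-only")),
                              ("single_vs_mixed", "sm", ("single", "mixed"))):
        sub = df.dropna(subset=[col])
        for cls in sorted(sub["atc_class"].unique()):
            inside = sub[sub["atc_class"] == cls]
            outside = sub[sub["atc_class"] != cls]
            table = np.array([
                [(inside[col] == levels[0]).sum(), (inside[col] == levels[1]).sum()],
                [(outside[col] == levels[0]).sum(), (outside[col] == levels[1]).sum()],
            ])
            if table[0].min() < config.min_class_count:
                continue
            stat, p = chi2_2x2(table)
            rows.append({"atc_class": cls, "test": test, "statistic": stat, "p": p,
                         "n_in_class": int(table[0].sum())})
    out = pd.DataFrame(rows, columns=["atc_class", "test", "statistic", "p", "n_in_class"])
    if out.empty:
        import warnings

        warnings.warn("no ATC classes survive the count filter", stacklevel=2)
        out["significant"] = pd.Series(dtype=bool)
        return out
    n_tests = config.n_tests if config.n_tests else len(out)
    out["significant"] = out["p"] < config.alpha / n_tests
    return out


def drug_sex_profiles(pairs: pd.DataFrame, categories: pd.DataFrame,
                      min_studies: int = 3, biased_high: float = 2 / 3,
                      biased_low: float = 1 / 3) -> pd.DataFrame:
    """Per-drug fractions of female-only / male-only / mixed studies.

    A drug is flagged biased when it has at least ``min_studies`` studies
    and one single-sex fraction exceeds ``biased_high`` while the other is
    below ``biased_low``.
    """
    cat_of = categories.set_index("study_id")["category"]
    rows = []
    for drug, g in pairs.groupby("drug_id", sort=True):
        cats = g["study_id"].map(cat_of).dropna()
        cats = cats[cats != "unlabeled"]
        n = len(cats)
        if n == 0:
            continue
        f = float((cats == "female-only").mean())
        m = float((cats == "male-only").mean())
        x = 1.0 - f - m
        biased = n >= min_studies and (
            (f > biased_high and m < biased_low) or (m > biased_high and f < biased_low))
        rows.append({"drug_id": drug, "n_studies": n, "frac_female_only": f,
                     "frac_male_only": m, "frac_other": x, "biased": bool(biased)})
    return pd.DataFrame(rows, columns=["drug_id", "n_studies", "frac_female_only",
                                       "frac_male_only", "frac_other", "biased"])
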