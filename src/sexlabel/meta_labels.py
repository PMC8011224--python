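"""Metadata sex-label extraction and study sex categories.

Sample-level labels are pulled from attribute key/value pairs (keys that
mention sex/gender, plus values with a whole-word male/female match) and
normalized to a closed vocabulary.  Studies are then assigned one of six
categories from the composition of their sample labels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

FEMALE = "female"
MALE = "male"
MIXED = "mixed"
UNLABELED = "unlabeled"

SEX_LABELS = (FEMALE, MALE, MIXED, UNLABELED)

STUDY_CATEGORIES = (
    "unlabeled", "female-only", "male-only", "mostly-female", "mostly-male", "mixed",
)

_KEY_RE = re.compile(r"sex|gender", re.IGNORECASE)
_FEMALE_RE = re.compile(r"\bfemales?\b", re.IGNORECASE)
_MALE_RE = re.compile(r"\bmales?\b", re.IGNORECASE)
_MIX_HINT_RE = re.compile(r"\b(pool(ed)?|mix(ed)?|both)\b", re.IGNORECASE)

# Canonical single-token forms.  The dictionary is an explicit, configurable
# extension of the common-variant mapping; anything unmapped -> unlabeled.
_VALUE_MAP = {
    "f": FEMALE, "female": FEMALE, "fem": FEMALE, "woman": FEMALE,
    "women": FEMALE, "girl": FEMALE, "xx": FEMALE,
    "m": MALE, "male": MALE, "man": MALE, "men": MALE, "boy": MALE, "xy": MALE,
    "mixed": MIXED, "pooled": MIXED, "both": MIXED,
}


@dataclass(frozen=True)
class CategoryConfig:
    """Thresholds for study categorization."""

    majority_cutoff: float = 0.8
    small_study_max: int = 60
    min_labeled_large: int = 30

    def __post_init__(self) -> None:
        if not 0.5 < self.majority_cutoff < 1.0:
            raise ValueError("majority_cutoff must be in (0.5, 1)")


def extract_sex_attributes(attributes: Mapping[str, str] | Iterable[tuple[str, str]]) -> list[str]:
    """Return attribute values that are candidate sex labels.

    A value is a candidate if its key contains "sex" or "gender"
    (case-insensitive), or if the value itself contains a whole-word match
    to "male" or "female".
    """
    items = attributes.items() if isinstance(attributes, Mapping) else attributes
    out = []
    for key, value in items:
        value = str(value)
        if _KEY_RE.search(str(key)) or _FEMALE_RE.search(value) or _MALE_RE.search(value):
            out.append(value)
    return out


def normalize_sex_value(raw: str) -> str:
    """Map a raw metadata string to female / male / mixed / unlabeled.

    Whole-word matching is used throughout so "female" is never consumed by
    the substring "male".  A value mentioning both sexes (or an explicit
    pooled/mixed marker with one sex word) maps to "mixed".
    """
    if raw is None:
        return UNLABELED
    s = str(raw).strip().strip(".,;:()[]\"'").strip().lower()
    if not s:
        return UNLABELED
    if s in _VALUE_MAP:
        return _VALUE_MAP[s]
    has_f = bool(_FEMALE_RE.search(s))
    has_m = bool(_MALE_RE.search(s))
    if has_f and has_m:
        return MIXED
    if (has_f or has_m) and _MIX_HINT_RE.search(s):
        return MIXED
    if has_f:
        return FEMALE
    if has_m:
        return MALE
    return UNLABELED


def sex_label_for_sample(attributes: Mapping[str, str] | Iterable[tuple[str, str]]) -> str:
    """Extract + normalize a single sample's sex label.

    Candidate values are normalized in order; the first informative label
    wins.  Conflicting female/male candidates yield "mixed" only when a
    single value mentions both; across attributes we keep the first.
    """
    for value in extract_sex_attributes(attributes):
        label = normalize_sex_value(value)
        if label != UNLABELED:
            return label
    return UNLABELED


def categorize_study(labels: Iterable[str], total: int,
                     config: CategoryConfig = CategoryConfig()) -> str:
    """Assign a study category from its sample-label multiset.

    The unlabeled rule is applied first with strict comparisons: studies of
    up to ``small_study_max`` samples with fewer than half labeled, or
    larger studies with fewer than ``min_labeled_large`` labeled, are
    "unlabeled".  Pooled ("mixed") samples count as labeled but are excluded
    from the male/female proportion.
    """
    if total <= 0:
        raise ValueError("study has zero samples")
    labels = list(labels)
    if len(labels) > total:
        raise ValueError("more labels than samples")
    n_f = sum(1 for l in labels if l == FEMALE)
    n_m = sum(1 for l in labels if l == MALE)
    n_x = sum(1 for l in labels if l == MIXED)
    n_labeled = n_f + n_m + n_x
    if total <= config.small_study_max:
        if n_labeled < total / 2:
            return "unlabeled"
    elif n_labeled < config.min_labeled_large:
        return "unlabeled"
    if n_f + n_m == 0:
        return "mixed"
    if n_m == 0:
        return "female-only"
    if n_f == 0:
        return "male-only"
    if n_m / (n_f + n_m) > config.majority_cutoff:
        return "mostly-male"
    if n_f / (n_f + n_m) > config.majority_cutoff:
        return "mostly-female"
    return "mixed"


def label_metadata(meta: pd.DataFrame,
                   config: CategoryConfig = CategoryConfig()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label every sample and categorize every study in a long-format table.

    ``meta`` columns: sample_id, study_id, key, value (platform optional).
    Returns (per-sample table, per-study table).
    """
    required = {"sample_id", "study_id", "key", "value"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")

    sample_rows = []
    grouped = meta.groupby("sample_id", sort=True)
    study_of = {}
    for sample_id, g in grouped:
        label = sex_label_for_sample(zip(g["key"], g["value"]))
        sample_rows.append((sample_id, label))
        study_of[sample_id] = g["study_id"].iloc[0]
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "metadata_sex"])
    samples["study_id"] = samples["sample_id"].map(study_of)

    study_rows = []
    for study_id, g in samples.groupby("study_id", sort=True):
        labels = [l for l in g["metadata_sex"] if l != UNLABELED]
        cat = categorize_study(labels, len(g), config)
        study_rows.append((study_id, len(g), len(labels), cat))
    studies = pd.DataFrame(study_rows, columns=["study_id", "n_samples", "n_labeled", "category"])
    return samples[["sample_id", "study_id", "metadata_sex"]], studies


def run(meta_path: str | Path, outdir: str | Path,
        config: CategoryConfig = CategoryConfig()) -> tuple[Path, Path]:
    """CLI entry: read a metadata TSV, write per-sample and per-study tables."""
    meta = pd.read_csv(meta_path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    samples, studies = label_metadata(meta, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sp = outdir / "sample_sex.tsv"
    tp = outdir / "study_categories.tsv"
    samples.to_csv(sp, sep="\t", index=False)
    studies.to_csv(tp, sep="\t", index=False)
    return sp, tp
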