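"""Entity normalization: cell-line and drug lexicons, source types,
and drug-mention / drug-exposure study labeling.

Matching is lexical: terms are lowercased, tokenized on whitespace and
punctuation (internal hyphens are kept so names like "kyse-30" survive),
and a punctuation-stripped variant of every term is indexed as well.
Sample values are mapped through three attribute tiers of decreasing
specificity; within a tier, whole-value exact matches are tried before
n-gram (n = 1..3) matches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")
_NON_ALNUM_RE = re.compile(r"[^a-z0-9]+")

SOURCE_TYPES = (
    "tissue", "stem_cell", "xenograft", "cancer_cell",
    "cell_line_named", "cell_line_unnamed", "primary_cell", "other",
)


def _load_list(name: str) -> list[str]:
    text = resources.files("sexlabel.data").joinpath(name).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def default_stopwords() -> set[str]:
    return set(_load_list("stopwords.txt"))


def default_mouse_strains() -> set[str]:
    return set(_load_list("mouse_strains.txt"))


def default_control_terms() -> list[str]:
    return _load_list("control_terms.txt")


def norm_term(term: str) -> str:
    """Lowercase and collapse whitespace; strip surrounding punctuation."""
    s = str(term).strip().lower()
    s = re.sub(r"\s+", " ", s)
    return s.strip(".,;:()[]\"'")


def strip_punct(term: str) -> str:
    """Remove everything but alphanumerics (the punctuation-blind key)."""
    return _NON_ALNUM_RE.sub("", str(term).lower())


def tokenize(text: str) -> list[str]:
    """Lowercased tokens; internal hyphens are preserved."""
    return _TOKEN_RE.findall(str(text).lower())


def ngrams(tokens: list[str], n: int) -> list[tuple[int, str]]:
    """(start index, joined n-gram) pairs."""
    return [(i, " ".join(tokens[i:i + n])) for i in range(len(tokens) - n + 1)]


def _term_ok(term: str, stopwords: set[str], min_len: int = 3,
             strains: set[str] | None = None) -> bool:
    if len(term) < min_len:
        return False
    if term.isdigit():
        return False
    if term in stopwords:
        return False
    if strains and term in strains:
        return False
    return True


# ---------------------------------------------------------------------------
# Cell-line lexicon
# ---------------------------------------------------------------------------

@dataclass
class CellLineLexicon:
    """Normalized term -> accessions, with collision bookkeeping."""

    term_map: dict[str, set[str]]
    punct_map: dict[str, set[str]]  # punctuation-stripped key -> accessions
    info: dict[str, dict]  # accession -> name/donor_sex/recorded_sex/parent
    collisions: dict[str, list] = field(default_factory=dict)

    def lookup(self, term: str) -> set[str]:
        term = norm_term(term)
        hits = self.term_map.get(term)
        if hits:
            return set(hits)
        return set(self.punct_map.get(strip_punct(term), set()))


def build_cell_line_lexicon(records: pd.DataFrame,
                            stopwords: set[str] | None = None,
                            mouse_strains: set[str] | None = None) -> CellLineLexicon:
    """Build the lexicon with the duplicate-name and synonym-collision rules.

    - identically named lines sharing a parent collapse to the parent;
    - a name shared by several accessions (exactly or modulo punctuation)
      maps to all of them;
    - a synonym colliding with another line's canonical name is dropped in
      favour of the name's own accession(s);
    - all-numeric, short (< 3 chars), stop-word, and mouse-strain terms are
      removed.
    """
    stopwords = default_stopwords() if stopwords is None else stopwords
    mouse_strains = default_mouse_strains() if mouse_strains is None else mouse_strains

    recs = records.fillna("").copy()
    recs["norm_name"] = recs["name"].map(norm_term)

    # Collapse identically named children sharing a parent onto the parent.
    effective: dict[str, str] = {}
    for name, g in recs.groupby("norm_name"):
        accs = list(g["accession"])
        parents = set(g["parent_id"]) - {""}
        if len(accs) > 1 and len(parents) == 1:
            parent = parents.pop()
            for acc in accs:
                effective[acc] = parent
    recs["effective"] = [effective.get(a, a) for a in recs["accession"]]

    info = {
        row.accession: {
            "name": row.name_, "donor_sex": row.donor_sex,
            "recorded_sex": row.recorded_sex, "parent_id": row.parent_id,
        }
        for row in recs.rename(columns={"name": "name_"}).itertuples()
    }

    name_of: dict[str, set[str]] = {}
    for row in recs.itertuples():
        if _term_ok(row.norm_name, stopwords, strains=mouse_strains):
            name_of.setdefault(row.norm_name, set()).add(row.effective)
    name_punct: dict[str, set[str]] = {}
    for name, accs in name_of.items():
        name_punct.setdefault(strip_punct(name), set()).update(accs)

    collisions: dict[str, list] = {"same_name": [], "same_name_punct": [],
                                   "synonym_vs_name": []}
    for name, accs in name_of.items():
        if len(accs) > 1:
            collisions["same_name"].append((name, sorted(accs)))
    for key, accs in name_punct.items():
        if len(accs) > 1:
            collisions["same_name_punct"].append((key, sorted(accs)))

    term_map: dict[str, set[str]] = {n: set(a) for n, a in name_of.items()}
    punct_map: dict[str, set[str]] = {k: set(a) for k, a in name_punct.items()}

    for row in recs.itertuples():
        syns = [norm_term(s) for s in str(row.synonyms).split("|") if s.strip()]
        for syn in syns:
            if not _term_ok(syn, stopwords, strains=mouse_strains):
                continue
            owner_accs = name_of.get(syn) or name_punct.get(strip_punct(syn))
            if owner_accs and row.effective not in owner_accs:
                # synonym collides with another line's canonical name
                collisions["synonym_vs_name"].append((syn, row.effective, sorted(owner_accs)))
                continue
            term_map.setdefault(syn, set()).add(row.effective)
            punct_map.setdefault(strip_punct(syn), set()).add(row.effective)
    return CellLineLexicon(term_map=term_map, punct_map=punct_map,
                           info=info, collisions=collisions)


def _attr_tiers(attributes: Mapping[str, str] | Iterable[tuple[str, str]]
                ) -> tuple[list[str], list[str], list[str]]:
    items = list(attributes.items() if isinstance(attributes, Mapping) else attributes)
    t1, t2, t3 = [], [], []
    for key, value in items:
        k, v = str(key).lower(), str(value)
        vl = v.lower()
        if "cell" in k and "line" in k:
            t1.append(v)
        elif "cell" in vl and "line" in vl:
            t2.append(v)
        elif re.search(r"\bcells?\b", k) or re.search(r"\bcells?\b", vl):
            t3.append(v)
    return t1, t2, t3


def map_sample_to_cell_lines(attributes, lexicon: CellLineLexicon,
                             _trace: list | None = None) -> tuple[set[str], int]:
    """Map one sample's attributes to cell-line accessions.

    Returns (accessions, tier) with tier in {1, 2, 3}; (set(), 0) when
    nothing matches.  ``_trace`` (tests only) records the tiers consulted.
    """
    tiers = _attr_tiers(attributes)
    for tier_no, values in enumerate(tiers, start=1):
        if _trace is not None and values:
            _trace.append(tier_no)
        hits: set[str] = set()
        # whole-value exact matches first
        for v in values:
            nv = norm_term(v)
            if len(nv) >= 3:
                hits |= lexicon.lookup(nv)
        if hits:
            return hits, tier_no
        # n-gram fallback within the same tier
        for v in values:
            if len(norm_term(v)) <= 3:
                continue
            tokens = tokenize(v)
            covered: set[int] = set()
            for n in (3, 2, 1):
                for start, gram in ngrams(tokens, n):
                    span = set(range(start, start + n))
                    if span & covered:
                        continue
                    found = lexicon.lookup(gram)
                    if found:
                        hits |= found
                        covered |= span
        if hits:
            return hits, tier_no
    return set(), 0


_SOURCE_RULES: list[tuple[str, re.Pattern]] = [
    ("xenograft", re.compile(r"\bxenografts?\b")),
    ("stem_cell", re.compile(r"\bstem cells?\b|\bipscs?\b|\bescs?\b|\bembryonic stem\b")),
    ("primary_cell", re.compile(r"\bprimary (cells?|cultures?)\b")),
    ("cancer_cell", re.compile(r"\b(cancer|tumou?r) cells?\b")),
    ("cell_line", re.compile(r"\bcell lines?\b")),
    ("tissue", re.compile(r"\btissues?\b|\bbiops(y|ies)\b")),
]


def classify_source_type(attributes, cell_hits: set[str]) -> str:
    """Assign a source type by keyword precedence.

    Precedence: xenograft > stem cell > primary cell > cancer cell >
    cell line (named when an accession is attached, else unnamed) >
    tissue > other.  A cell-line accession alone (matched without the
    literal phrase) still yields cell_line_named.
    """
    items = attributes.items() if isinstance(attributes, Mapping) else attributes
    text = " ".join(f"{k} {v}" for k, v in items).lower()
    for source, pattern in _SOURCE_RULES:
        if pattern.search(text):
            if source == "cell_line":
                return "cell_line_named" if cell_hits else "cell_line_unnamed"
            return source
    if cell_hits:
        return "cell_line_named"
    return "other"


# ---------------------------------------------------------------------------
# Drug lexicon
# ---------------------------------------------------------------------------

@dataclass
class DrugLexicon:
    term_map: dict[str, set[str]]
    atc_of: dict[str, list[str]]
    name_of: dict[str, str]
    control_terms: set[str]


def build_drug_lexicon(records: pd.DataFrame,
                       control_terms: Iterable[str] | None = None,
                       stopwords: set[str] | None = None) -> DrugLexicon:
    """Index drug names/synonyms (length > 3, no stop words) and ATC codes.

    The control vocabulary is stored verbatim — short control terms such as
    "na" are kept because they are matched against the control list, not the
    drug term index.
    """
    stopwords = default_stopwords() if stopwords is None else stopwords
    control = default_control_terms() if control_terms is None else list(control_terms)
    term_map: dict[str, set[str]] = {}
    atc_of: dict[str, list[str]] = {}
    name_of: dict[str, str] = {}
    for row in records.fillna("").itertuples():
        atc_of[row.drug_id] = [c for c in str(row.atc_codes).split("|") if c]
        name_of[row.drug_id] = row.name
        terms = [row.name] + [s for s in str(row.synonyms).split("|") if s.strip()]
        for term in terms:
            t = norm_term(term)
            if len(t) <= 3 or t in stopwords or t.isdigit():
                continue
            term_map.setdefault(t, set()).add(row.drug_id)
    return DrugLexicon(term_map=term_map, atc_of=atc_of, name_of=name_of,
                       control_terms={norm_term(c) for c in control})


def map_text_to_drugs(text: str, lexicon: DrugLexicon) -> tuple[set[str], bool]:
    """n-gram (n = 1..3) drug and control-term matching over free text.

    Longer matches shadow their sub-grams for drug lookups; control matching
    is independent, so one text can map to both a drug and a control term.
    """
    if not text or not str(text).strip():
        return set(), False
    tokens = tokenize(text)
    drugs: set[str] = set()
    covered: set[int] = set()
    control = False
    for n in (3, 2, 1):
        for start, gram in ngrams(tokens, n):
            if gram in lexicon.control_terms:
                control = True
            span = set(range(start, start + n))
            if span & covered:
                continue
            hit = lexicon.term_map.get(gram)
            if hit:
                drugs |= hit
                covered |= span
    return drugs, control


def label_drug_studies(studies: pd.DataFrame, samples: pd.DataFrame,
                       lexicon: DrugLexicon) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label drug-mention studies and drug-exposure study-drug pairs.

    ``studies`` columns: study_id, title, description.
    ``samples`` columns: sample_id, study_id plus any of treatment /
    compound / title fields.
    A study is a *mention* study when its title+description maps to >= 1
    drug; it is an *exposure* study when a sample-level drug intersects the
    study-level drugs, and the reported pairs are that intersection.
    """
    sample_fields = [c for c in ("treatment", "compound", "title")
                     if c in samples.columns]
    mention_rows = []
    study_drugs: dict[str, set[str]] = {}
    for row in studies.fillna("").itertuples():
        text = f"{row.title} {row.description}"
        drugs, _ = map_text_to_drugs(text, lexicon)
        study_drugs[row.study_id] = drugs
        for d in sorted(drugs):
            mention_rows.append({"study_id": row.study_id, "drug_id": d})
    mentions = pd.DataFrame(mention_rows, columns=["study_id", "drug_id"])

    sample_drugs: dict[str, set[str]] = {}
    for row in samples.fillna("").itertuples():
        text = " ".join(str(getattr(row, f)) for f in sample_fields)
        drugs, _ = map_text_to_drugs(text, lexicon)
        if drugs:
            sample_drugs.setdefault(row.study_id, set()).update(drugs)
    exposure_rows = []
    for study_id, s_drugs in sorted(sample_drugs.items()):
        overlap = s_drugs & study_drugs.get(study_id, set())
        for d in sorted(overlap):
            exposure_rows.append({"study_id": study_id, "drug_id": d})
    exposures = pd.DataFrame(exposure_rows, columns=["study_id", "drug_id"])
    return mentions, exposures


# ---------------------------------------------------------------------------
# File readers
# ---------------------------------------------------------------------------

def read_cell_lexicon(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_drug_lexicon(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def map_metadata_to_cell_lines(meta: pd.DataFrame,
                               lexicon: CellLineLexicon) -> pd.DataFrame:
    """Map every sample in a long-format metadata table to cell lines.

    Returns sample_id, accessions (pipe-joined), tier, source_type.
    """
    rows = []
    for sample_id, g in meta.groupby("sample_id", sort=True):
        attrs = list(zip(g["key"], g["value"]))
        hits, tier = map_sample_to_cell_lines(attrs, lexicon)
        source = classify_source_type(attrs, hits)
        rows.append({"sample_id": sample_id, "accessions": "|".join(sorted(hits)),
                     "tier": tier, "source_type": source})
    return pd.DataFrame(rows)
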