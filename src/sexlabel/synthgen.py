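"""Synthetic expression + metadata corpora with known ground truth.

Generates corpora whose statistical structure matches what the labeling
pipeline assumes: bimodal Y-gene expression between the sexes, elevated
X-escape expression in females, per-study batch shifts, platform groups,
pooled samples at intermediate mixing fractions, cell lines with Y loss,
metadata missingness, and injected sex-label swaps.  Ground truth is kept
in a separate table that pipeline stages never read.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FEMALE = "female"
MALE = "male"
POOLED = "pooled"

_SEX_VALUE_VARIANTS = {
    FEMALE: ["female", "F", "Female", "f"],
    MALE: ["male", "M", "Male", "m"],
}


class ConfigError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic corpus.

    Proportions must lie in [0, 1]; counts must be >= 1.  The seed fully
    determines the generated corpus.
    """

    n_studies: int = 200
    samples_per_study: tuple[int, int] = (8, 24)
    frac_single_sex: float = 0.4
    frac_female_only_of_single: float = 0.5
    n_y_genes: int = 6
    n_xescape_genes: int = 8
    n_xinactive_genes: int = 10
    y_effect: float = 4.0
    xescape_effect: float = 1.5
    study_sd: float = 0.5
    noise_sd: float = 0.5
    swap_rate: float = 0.0
    missing_rate: float = 0.1
    frac_pooled: float = 0.0
    n_platforms: int = 3
    null_platforms: int = 0
    n_cell_lines: int = 0
    frac_cell_line: float = 0.0
    cellline_yloss_rate: float = 0.0
    data_type: str = "microarray"
    seed: int = 0

    def __post_init__(self) -> None:
        props = {
            "frac_single_sex": self.frac_single_sex,
            "frac_female_only_of_single": self.frac_female_only_of_single,
            "swap_rate": self.swap_rate,
            "missing_rate": self.missing_rate,
            "frac_pooled": self.frac_pooled,
            "frac_cell_line": self.frac_cell_line,
            "cellline_yloss_rate": self.cellline_yloss_rate,
        }
        for name, value in props.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        counts = {
            "n_studies": self.n_studies,
            "n_y_genes": self.n_y_genes,
            "n_xescape_genes": self.n_xescape_genes,
            "n_xinactive_genes": self.n_xinactive_genes,
            "n_platforms": self.n_platforms,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigError(f"{name} must be >= 1, got {value}")
        lo, hi = self.samples_per_study
        if lo < 1 or hi < lo:
            raise ConfigError(f"invalid samples_per_study range {self.samples_per_study}")
        if self.data_type not in ("microarray", "rnaseq"):
            raise ConfigError(f"data_type must be microarray or rnaseq, got {self.data_type}")
        if self.null_platforms >= self.n_platforms:
            raise ConfigError("null_platforms must be < n_platforms")


@dataclass
class Corpus:
    """A generated corpus: expression, metadata, gene map, and ground truth."""

    expression: pd.DataFrame  # samples x genes, index = sample_id
    meta: pd.DataFrame  # long format: sample_id, study_id, platform, key, value
    genes: pd.DataFrame  # gene_id, chromosome, xi_status
    truth: pd.DataFrame  # sample_id, study_id, true_sex, ...
    config: SimConfig = field(repr=False, default=None)


def _gene_table(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for i in range(cfg.n_y_genes):
        rows.append((f"YG{i:03d}", "Y", "unknown"))
    for i in range(cfg.n_xescape_genes):
        rows.append((f"XE{i:03d}", "X", "escape"))
    for i in range(cfg.n_xinactive_genes):
        rows.append((f"XI{i:03d}", "X", "inactive"))
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "xi_status"])


def generate_corpus(cfg: SimConfig) -> Corpus:
    """Generate a synthetic corpus according to ``cfg``.

    Y genes sit near a low floor in true females and are shifted up by
    ``y_effect`` in true males; X-escape genes are shifted up by
    ``xescape_effect`` in females.  Pooled samples are a
    u ~ Uniform(0.2, 0.8) mixture of the two sex profiles.  Metadata sex
    equals true sex except for ``swap_rate`` flips and ``missing_rate``
    blanks.  Studies on the first ``null_platforms`` platforms are
    generated with zero sex effects (for platform-QC testing).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_table(cfg)
    gene_ids = genes["gene_id"].to_numpy()
    is_y = (genes["chromosome"] == "Y").to_numpy()
    is_xe = (genes["xi_status"] == "escape").to_numpy()

    baseline = np.where(is_y, rng.uniform(1.0, 2.0, len(gene_ids)),
                        rng.uniform(5.0, 9.0, len(gene_ids)))

    cell_sexes = rng.integers(0, 2, cfg.n_cell_lines) if cfg.n_cell_lines else np.array([], int)
    cell_names = [f"SYN-{i:02d}" for i in range(cfg.n_cell_lines)]

    expr_rows, meta_rows, truth_rows, sample_ids = [], [], [], []
    for s in range(cfg.n_studies):
        study_id = f"ST{s:05d}"
        n = int(rng.integers(cfg.samples_per_study[0], cfg.samples_per_study[1] + 1))
        platform = f"P{int(rng.integers(cfg.n_platforms)):02d}"
        null_platform = int(platform[1:]) < cfg.null_platforms
        batch = rng.normal(0.0, cfg.study_sd)

        single = rng.random() < cfg.frac_single_sex
        if single:
            study_sex = 0 if rng.random() < cfg.frac_female_only_of_single else 1
            sexes = np.full(n, study_sex)
        else:
            sexes = rng.integers(0, 2, n)

        for j in range(n):
            sample_id = f"S{s:05d}.{j:03d}"
            sample_ids.append(sample_id)
            sex = int(sexes[j])
            pooled = (not single) and rng.random() < cfg.frac_pooled
            u_male = rng.uniform(0.2, 0.8) if pooled else float(sex)

            cell_line = ""
            yloss = False
            if cfg.n_cell_lines and not pooled and rng.random() < cfg.frac_cell_line:
                ci = int(rng.integers(cfg.n_cell_lines))
                cell_line = cell_names[ci]
                sex = int(cell_sexes[ci])
                u_male = float(sex)
                if sex == 1 and rng.random() < cfg.cellline_yloss_rate:
                    yloss = True

            y_eff = 0.0 if (null_platform or yloss) else cfg.y_effect * u_male
            xe_eff = 0.0 if null_platform else cfg.xescape_effect * (1.0 - u_male)
            mu = baseline + batch
            mu = mu + np.where(is_y, y_eff, 0.0) + np.where(is_xe, xe_eff, 0.0)
            x = mu + rng.normal(0.0, cfg.noise_sd, len(gene_ids))
            if cfg.data_type == "rnaseq":
                x = rng.poisson(np.exp2(np.clip(x, 0.0, 30.0))).astype(float)
            expr_rows.append(x)

            true_sex = POOLED if pooled else (MALE if sex == 1 else FEMALE)
            swap = False
            meta_sex_rows = []
            if pooled:
                meta_sex_rows.append(("sex", "pooled male and female"))
            else:
                if rng.random() < cfg.missing_rate:
                    pass  # no sex attribute at all
                else:
                    reported = true_sex
                    if rng.random() < cfg.swap_rate:
                        swap = True
                        reported = FEMALE if true_sex == MALE else MALE
                    variant = _SEX_VALUE_VARIANTS[reported][int(rng.integers(4))]
                    key = "sex" if rng.random() < 0.8 else "gender"
                    meta_sex_rows.append((key, variant))
            for key, value in meta_sex_rows:
                meta_rows.append((sample_id, study_id, platform, key, value))
            if cell_line:
                meta_rows.append((sample_id, study_id, platform, "cell line", cell_line))
            meta_rows.append((sample_id, study_id, platform, "tissue", "liver"))

            truth_rows.append(
                (sample_id, study_id, true_sex, round(u_male, 6), swap,
                 cell_line, yloss, "single-sex" if single else "mixed")
            )

    expression = pd.DataFrame(np.asarray(expr_rows), index=sample_ids, columns=gene_ids)
    expression.index.name = "sample_id"
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "study_id", "platform", "key", "value"])
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "study_id", "true_sex", "frac_male", "swap",
                 "cell_line", "yloss", "study_type"],
    )
    return Corpus(expression=expression, meta=meta, genes=genes, truth=truth, config=cfg)


def write_corpus(corpus: Corpus, outdir: str | Path, matrix_market: bool = False) -> dict[str, Path]:
    """Write a corpus to TSV files (optionally matrix-market for expression).

    Ground truth goes to its own file; pipeline stages must not read it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if matrix_market:
        from scipy.io import mmwrite

        mtx = outdir / "expr.mtx"
        mmwrite(str(mtx), corpus.expression.to_numpy())
        (outdir / "expr_rows.txt").write_text("\n".join(corpus.expression.index) + "\n")
        (outdir / "expr_cols.txt").write_text("\n".join(corpus.expression.columns) + "\n")
        paths["expr"] = mtx
    else:
        paths["expr"] = outdir / "expr.tsv"
        corpus.expression.to_csv(paths["expr"], sep="\t", float_format="%.6f")
    paths["meta"] = outdir / "meta.tsv"
    corpus.meta.to_csv(paths["meta"], sep="\t", index=False)
    paths["genes"] = outdir / "genes.tsv"
    corpus.genes.to_csv(paths["genes"], sep="\t", index=False)
    paths["truth"] = outdir / "truth.tsv"
    corpus.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read an expression TSV (first column sample id) or matrix-market trio."""
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        raw = mmread(path)
        mat = np.asarray(raw.todense() if hasattr(raw, "todense") else raw)
        rows = (path.parent / "expr_rows.txt").read_text().split()
        cols = (path.parent / "expr_cols.txt").read_text().split()
        return pd.DataFrame(mat, index=rows, columns=cols)
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


# ---------------------------------------------------------------------------
# Lexicon fixtures
# ---------------------------------------------------------------------------

#: Control vocabulary used by the drug-mapping stage (shipped verbatim).
CONTROL_TERMS = [
    "none", "control", "untreated", "dmso", "na", "placebo", "saline", "pbs",
    "mock", "baseline", "unstimulated", "etoh", "ethanol", "ctrl",
    "non-treated", "vehicle", "ctl", "no treatment",
]


def generate_lexicon_fixtures(seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Build cell-line and drug lexicon fixtures with deliberate edge cases.

    Edge cases covered: duplicated names across accessions, punctuation
    variants, a synonym colliding with another line's canonical name,
    all-numeric names, identically named children sharing a parent, drug
    names <= 3 characters, multi-word drug names for 2/3-gram matching,
    and the full control vocabulary.
    """
    rng = np.random.default_rng(seed)

    cell_rows = [
        # accession, name, synonyms (|), donor_sex, recorded_sex, parent
        ("CVCL_0001", "HeLa", "hela s3|henrietta", "female", "female", ""),
        ("CVCL_0002", "KG-1", "kg1", "male", "male", ""),
        ("CVCL_0003", "KG-1", "1234", "male", "", ""),  # duplicate name + numeric synonym
        ("CVCL_0004", "KYSE-30", "kyse30", "male", "male", ""),
        ("CVCL_0005", "A549", "a 549", "male", "male", ""),
        ("CVCL_0006", "THP-1", "thp1|tamm", "male", "male", ""),
        ("CVCL_0007", "HaCaT", "keratinocyte line hacat", "male", "", ""),
        ("CVCL_0008", "HCT-116", "hct 116|hct116", "male", "male", ""),
        ("CVCL_0009", "MCF-7", "mcf7|ibmf-7", "female", "female", ""),
        # synonym of CVCL_0010 collides with the canonical name of CVCL_0006 (THP-1)
        ("CVCL_0010", "U-937", "thp-1|u937", "male", "male", ""),
        # identically named children sharing a parent -> collapse to parent
        ("CVCL_0011", "Clone-9", "", "male", "", "CVCL_0013"),
        ("CVCL_0012", "Clone-9", "", "male", "", "CVCL_0013"),
        ("CVCL_0013", "Parent-9", "", "male", "male", ""),
        ("CVCL_0014", "OCI-Ly7", "ly7", "male", "male", ""),
        ("CVCL_0015", "22", "", "male", "", ""),  # all-numeric name, removed
        ("CVCL_0016", "Jurkat", "jm", "male", "male", ""),  # synonym < 3 chars, removed
    ]
    for i in range(8):  # filler lines so fixtures are not degenerate
        cell_rows.append(
            (f"CVCL_1{i:03d}", f"SYN-{i:02d}", f"syn{i:02d}",
             "male" if rng.random() < 0.5 else "female", "", "")
        )
    cells = pd.DataFrame(
        cell_rows,
        columns=["accession", "name", "synonyms", "donor_sex", "recorded_sex", "parent_id"],
    )

    drug_rows = [
        ("DB0001", "tamoxifen", "tamoxifen citrate|nolvadex", "L02BA01"),
        ("DB0002", "fluoxetine", "prozac", "N06AB03"),
        ("DB0003", "ace", "", "C09AA"),  # 3 chars -> dropped entirely
        ("DB0004", "haloperidol", "haldol", "N05AD01"),
        ("DB0005", "all-trans retinoic acid", "tretinoin|atra", "L01XF01|D10AD01"),
        ("DB0006", "enzalutamide", "xtandi", "L02BB04"),
        ("DB0007", "doxorubicin", "adriamycin", "L01DB01"),
        ("DB0008", "estradiol valerate", "", "G03CA03"),
        ("DB0009", "memantine", "namenda", "N06DX01"),
        ("DB0010", "dimethyl sulfoxide", "dmso", "G04BX13"),  # collides with control term
        ("DB0011", "bleomycin", "", "L01DC01"),
        ("DB0012", "carbamazepine", "tegretol", "N03AF01"),
    ]
    drugs = pd.DataFrame(drug_rows, columns=["drug_id", "name", "synonyms", "atc_codes"])
    return cells, drugs, list(CONTROL_TERMS)


def write_lexicon_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the lexicon fixtures as TSV / plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells, drugs, controls = generate_lexicon_fixtures(seed)
    paths = {
        "cells": outdir / "cells.tsv",
        "drugs": outdir / "drugs.tsv",
        "controls": outdir / "control_terms.txt",
    }
    cells.to_csv(paths["cells"], sep="\t", index=False)
    drugs.to_csv(paths["drugs"], sep="\t", index=False)
    paths["controls"].write_text("\n".join(controls) + "\n")
    return paths


def config_from_dict(d: dict) -> SimConfig:
    """Build a :class:`SimConfig` from a plain dict, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
    if "samples_per_study" in d:
        d = dict(d)
        d["samples_per_study"] = tuple(d["samples_per_study"])
    return SimConfig(**d)
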