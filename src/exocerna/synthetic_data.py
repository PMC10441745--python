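"""Synthetic plasma-exosome expression data with planted ceRNA structure.

Generates every input the downstream pipeline consumes: three per-class
abundance tables (lncRNA, miRNA, mRNA) over a shared case/control sample
axis, miRNA->lncRNA and miRNA->mRNA target tables, per-sample clinical
covariates with PANSS subscores, term->gene annotation sets, and a scored
PPI edge list.

The expression model is log-normal: each feature has a baseline log2
abundance, group effects and noise act additively on the log2 scale, and
abundances are the exponentiated values.  Planted ceRNA triplets follow
sponge logic: the miRNA shifts in one direction between groups while its
partner lncRNA and mRNA shift in the opposite direction, and the
corresponding target edges are always present.  Case samples carry a latent
severity factor that drives both PANSS scores and (at a configurable
correlation) the planted features' expression.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"

PANSS_COLUMNS = ("panss_positive", "panss_negative", "panss_general", "panss_total")

# PANSS subscale calibration: latent loadings sum to 18 so the total score
# centres near 75.6 with SD ~ 18.6; bounds are the instrument's ranges.
_PANSS_PARAMS = {
    "panss_positive": (19.0, 4.5, 1.2, 7.0, 49.0),
    "panss_negative": (19.0, 4.5, 1.2, 7.0, 49.0),
    "panss_general": (37.6, 9.0, 2.0, 16.0, 112.0),
}


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig field is invalid; names the field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror a two-arm design of 10 cases and 10 controls with five
    planted ceRNA axes at a two-fold-squared (|log2FC| = 2) group shift and
    log2-scale noise SD 0.5.
    """

    n_per_group: int = 10
    n_lncrna: int = 300
    n_mirna: int = 100
    n_mrna: int = 500
    n_triplets: int = 5
    planted_log2fc: float = 2.0
    noise_sigma: float = 0.5
    background_target_density: float = 0.02
    clinical_link_r: float = 0.8
    n_terms: int = 20
    genes_per_term: int = 15
    ppi_density: float = 0.005
    ppi_score_range: tuple[float, float] = (0.1, 0.9)
    mirna_direction: str = "down"  # direction of planted miRNAs in cases
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        for f in ("n_lncrna", "n_mirna", "n_mrna"):
            if getattr(self, f) < 1:
                raise ConfigurationError(f"{f} must be >= 1")
        if not 0 <= self.n_triplets <= min(self.n_lncrna, self.n_mirna, self.n_mrna):
            raise ConfigurationError(
                "n_triplets must be within [0, min(n_lncrna, n_mirna, n_mrna)]"
            )
        if self.noise_sigma <= 0:
            raise ConfigurationError("noise_sigma must be > 0")
        for f in ("background_target_density", "clinical_link_r", "ppi_density"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ConfigurationError(f"{f} must be in [0, 1]")
        lo, hi = self.ppi_score_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError("ppi_score_range must satisfy 0 <= lo <= hi <= 1")
        if self.n_terms < 1 or self.genes_per_term < 1:
            raise ConfigurationError("n_terms and genes_per_term must be >= 1")
        if self.genes_per_term > self.n_mrna:
            raise ConfigurationError("genes_per_term must not exceed n_mrna")
        if self.mirna_direction not in ("up", "down"):
            raise ConfigurationError("mirna_direction must be 'up' or 'down'")


@dataclass
class ExpressionBundle:
    """Three feature x sample abundance tables sharing one ordered sample axis."""

    lncrna: pd.DataFrame
    mirna: pd.DataFrame
    mrna: pd.DataFrame
    groups: pd.Series  # index = sample ids, values in {case, control}

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups.index)

    @property
    def classes(self) -> dict[str, pd.DataFrame]:
        return {"lncRNA": self.lncrna, "miRNA": self.mirna, "mRNA": self.mrna}

    def validate(self) -> None:
        samples = list(self.groups.index)
        ids: set[str] = set()
        for name, tab in self.classes.items():
            if list(tab.columns) != samples:
                raise ValueError(f"{name} table sample axis differs from group labels")
            if tab.isna().any().any():
                raise ValueError(f"{name} table contains missing values")
            if (tab.values < 0).any():
                raise ValueError(f"{name} table contains negative abundances")
            if tab.index.has_duplicates:
                raise ValueError(f"duplicate feature ids in {name} table")
            if ids & set(tab.index):
                raise ValueError("feature ids overlap across RNA classes")
            ids |= set(tab.index)


@dataclass(frozen=True)
class TargetTables:
    """miRNA->lncRNA and miRNA->mRNA predicted-target edge sets."""

    mir_to_lnc: frozenset[tuple[str, str]]
    mir_to_mrna: frozenset[tuple[str, str]]


@dataclass
class SimulatedData:
    """Everything one simulation run produces."""

    config: SimulationConfig
    bundle: ExpressionBundle
    targets: TargetTables
    clinical: pd.DataFrame
    annotations: dict[str, list[str]]
    ppi: pd.DataFrame
    planted: list[tuple[str, str, str]] = field(default_factory=list)


def _feature_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(n)]


def _simulate_class(
    rng: np.random.Generator,
    n_features: int,
    n_planted: int,
    shift: float,
    sigma: float,
    link_r: float,
    link_sign: float,
    z: np.ndarray,
    n_per_group: int,
) -> np.ndarray:
    """Log2-scale matrix (features x samples); cases first, controls second."""
    n = 2 * n_per_group
    baseline = rng.uniform(4.0, 10.0, size=n_features)
    log2 = baseline[:, None] + rng.normal(0.0, sigma, size=(n_features, n))
    if n_planted:
        # case-group shift for planted features
        log2[:n_planted, :n_per_group] += shift
        if link_r > 0:
            # replace planted case noise by a z-correlated draw of equal SD
            eps = rng.normal(0.0, 1.0, size=(n_planted, n_per_group))
            corr = link_sign * link_r * z + np.sqrt(1.0 - link_r**2) * eps
            log2[:n_planted, :n_per_group] = (
                baseline[:n_planted, None] + shift + sigma * corr
            )
    return log2


def _sample_pairs(
    rng: np.random.Generator, left: list[str], right: list[str], density: float
) -> set[tuple[str, str]]:
    """Bernoulli(density) over the full left x right grid."""
    if density <= 0:
        return set()
    mask = rng.random((len(left), len(right))) < density
    ii, jj = np.nonzero(mask)
    return {(left[i], right[j]) for i, j in zip(ii, jj)}


def generate_bundle(config: SimulationConfig) -> SimulatedData:
    """Generate all pipeline inputs from a validated configuration.

    Deterministic for a fixed config (including seed).  Planted triplet i
    links mir{i}, lnc{i} and gene{i}; the miRNA shifts by
    -planted_log2fc between groups when ``mirna_direction="down"`` (its
    partners by +planted_log2fc), mirrored for ``"up"``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    npg = config.n_per_group
    sample_ids = [f"FOS{i+1:02d}" for i in range(npg)] + [
        f"HC{i+1:02d}" for i in range(npg)
    ]
    groups = pd.Series([CASE] * npg + [CONTROL] * npg, index=sample_ids, name="group")

    lnc_ids = _feature_ids("lnc", config.n_lncrna)
    mir_ids = _feature_ids("mir", config.n_mirna)
    mrna_ids = _feature_ids("gene", config.n_mrna)

    # latent per-case severity factor; clinical scores are generated first and
    # planted features couple to the realized standardized PANSS total, so the
    # feature-severity correlation hits clinical_link_r without attenuation
    z_latent = rng.normal(0.0, 1.0, size=npg)
    clinical = _simulate_clinical(rng, sample_ids, groups, z_latent)
    total = clinical.loc[groups == CASE, "panss_total"].to_numpy(dtype=float)
    z = (total - total.mean()) / total.std()

    mir_sign = -1.0 if config.mirna_direction == "down" else 1.0
    partner_shift = -mir_sign * config.planted_log2fc
    mir_shift = mir_sign * config.planted_log2fc

    nt = config.n_triplets
    mats = {}
    for name, n_feat, shift, link_sign in (
        ("lncRNA", config.n_lncrna, partner_shift, np.sign(partner_shift) or 1.0),
        ("miRNA", config.n_mirna, mir_shift, np.sign(mir_shift) or 1.0),
        ("mRNA", config.n_mrna, partner_shift, np.sign(partner_shift) or 1.0),
    ):
        log2 = _simulate_class(
            rng, n_feat, nt, shift, config.noise_sigma,
            config.clinical_link_r, link_sign, z, npg,
        )
        mats[name] = np.exp2(log2)

    def _table(mat, ids):
        return pd.DataFrame(
            mat, index=pd.Index(ids, name="feature_id"), columns=sample_ids
        )

    bundle = ExpressionBundle(
        lncrna=_table(mats["lncRNA"], lnc_ids),
        mirna=_table(mats["miRNA"], mir_ids),
        mrna=_table(mats["mRNA"], mrna_ids),
        groups=groups,
    )

    # target tables: planted edges always present, background Bernoulli edges added
    planted = [(lnc_ids[i], mir_ids[i], mrna_ids[i]) for i in range(nt)]
    mir_to_lnc = {(mir_ids[i], lnc_ids[i]) for i in range(nt)}
    mir_to_mrna = {(mir_ids[i], mrna_ids[i]) for i in range(nt)}
    mir_to_lnc |= _sample_pairs(rng, mir_ids, lnc_ids, config.background_target_density)
    mir_to_mrna |= _sample_pairs(rng, mir_ids, mrna_ids, config.background_target_density)
    targets = TargetTables(frozenset(mir_to_lnc), frozenset(mir_to_mrna))

    annotations = _simulate_annotations(rng, config, mrna_ids, nt)
    ppi = _simulate_ppi(rng, config, mrna_ids, nt)

    return SimulatedData(
        config=config, bundle=bundle, targets=targets, clinical=clinical,
        annotations=annotations, ppi=ppi, planted=planted,
    )


def _simulate_clinical(
    rng: np.random.Generator,
    sample_ids: list[str],
    groups: pd.Series,
    z: np.ndarray,
) -> pd.DataFrame:
    npg = int((groups == CASE).sum())
    n = len(sample_ids)
    age = np.clip(rng.normal(34.0, 12.0, size=n), 18.0, 70.0).round(1)
    edu = np.clip(rng.normal(10.4, 3.4, size=n), 1.0, 22.0).round(1)
    # balanced sexes within each arm
    half = npg // 2
    sex_arm = np.array([0] * half + [1] * (npg - half))
    sex = np.concatenate([rng.permutation(sex_arm), rng.permutation(sex_arm)])
    rows = pd.DataFrame(
        {"sample_id": sample_ids, "group": groups.values, "age": age,
         "sex": sex, "education": edu}
    )
    for col, (mu, load, noise_sd, lo, hi) in _PANSS_PARAMS.items():
        score = np.clip(
            mu + load * z + rng.normal(0.0, noise_sd, size=npg), lo, hi
        ).round(1)
        rows[col] = np.concatenate([score, np.full(n - npg, np.nan)])
    rows["panss_total"] = (
        rows["panss_positive"] + rows["panss_negative"] + rows["panss_general"]
    )
    return rows.set_index("sample_id")


def _simulate_annotations(
    rng: np.random.Generator,
    config: SimulationConfig,
    mrna_ids: list[str],
    n_planted: int,
) -> dict[str, list[str]]:
    annotations: dict[str, list[str]] = {}
    planted_genes = mrna_ids[:n_planted]
    for t in range(config.n_terms):
        genes = list(
            rng.choice(mrna_ids, size=config.genes_per_term, replace=False)
        )
        if t == 0 and planted_genes:
            # guarantee one term concentrated on the planted mRNAs
            fill = [g for g in genes if g not in planted_genes]
            genes = planted_genes + fill[: max(0, config.genes_per_term - n_planted)]
        annotations[f"TERM{t:03d}"] = sorted(set(genes))
    return annotations


def _simulate_ppi(
    rng: np.random.Generator,
    config: SimulationConfig,
    mrna_ids: list[str],
    n_planted: int,
) -> pd.DataFrame:
    lo, hi = config.ppi_score_range
    rows: list[tuple[str, str, float]] = []
    # planted mRNAs form a high-confidence clique (scores well above 0.4)
    for i in range(n_planted):
        for j in range(i + 1, n_planted):
            rows.append((mrna_ids[i], mrna_ids[j], float(rng.uniform(0.7, 0.99))))
    n = len(mrna_ids)
    n_pairs = n * (n - 1) // 2
    k = rng.binomial(n_pairs, config.ppi_density)
    if k > 0:
        idx = rng.choice(n_pairs, size=k, replace=False)
        # map linear index to the (i, j) upper-triangle pair
        ii = (n - 2 - np.floor(
            np.sqrt(-8 * idx + 4 * n * (n - 1) - 7) / 2.0 - 0.5
        )).astype(int)
        jj = (idx + ii + 1 - n * (n - 1) // 2 + (n - ii) * ((n - ii) - 1) // 2).astype(int)
        for i, j, s in zip(ii, jj, rng.uniform(lo, hi, size=k)):
            if i < n_planted and j < n_planted:
                continue  # clique edges already emitted
            rows.append((mrna_ids[i], mrna_ids[j], float(s)))
    ppi = pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])
    return ppi.drop_duplicates(subset=["gene_a", "gene_b"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# File I/O: tab-delimited UTF-8 with headers (GMT excepted)

def write_outputs(data: SimulatedData, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, tab in data.bundle.classes.items():
        p = outdir / f"expression_{name.lower()}.tsv"
        tab.rename_axis("feature_id").to_csv(p, sep="\t", float_format="%.6g")
        paths[name] = p
    p = outdir / "metadata.tsv"
    data.clinical.to_csv(p, sep="\t")
    paths["metadata"] = p
    for name, pairs in (
        ("mir_to_lnc", data.targets.mir_to_lnc),
        ("mir_to_mrna", data.targets.mir_to_mrna),
    ):
        p = outdir / f"targets_{name}.tsv"
        pd.DataFrame(sorted(pairs), columns=["mirna_id", "target_id"]).to_csv(
            p, sep="\t", index=False
        )
        paths[name] = p
    p = outdir / "annotations.gmt"
    with open(p, "w", encoding="utf-8") as fh:
        for term in sorted(data.annotations):
            genes = "\t".join(data.annotations[term])
            fh.write(f"{term}\tsynthetic term\t{genes}\n")
    paths["annotations"] = p
    p = outdir / "ppi.tsv"
    data.ppi.sort_values(["gene_a", "gene_b"]).to_csv(
        p, sep="\t", index=False, float_format="%.4f"
    )
    paths["ppi"] = p
    p = outdir / "planted_triplets.tsv"
    pd.DataFrame(data.planted, columns=["lncrna_id", "mirna_id", "mrna_id"]).to_csv(
        p, sep="\t", index=False
    )
    paths["planted"] = p
    return paths


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_bundle(outdir: str | Path) -> tuple[ExpressionBundle, pd.DataFrame]:
    outdir = Path(outdir)
    clinical = read_metadata(outdir / "metadata.tsv")
    bundle = ExpressionBundle(
        lncrna=read_expression(outdir / "expression_lncrna.tsv"),
        mirna=read_expression(outdir / "expression_mirna.tsv"),
        mrna=read_expression(outdir / "expression_mrna.tsv"),
        groups=clinical["group"],
    )
    bundle.validate()
    return bundle, clinical


def read_targets(mir_to_lnc_path: str | Path, mir_to_mrna_path: str | Path) -> TargetTables:
    def _read(p: str | Path) -> frozenset[tuple[str, str]]:
        df = pd.read_csv(p, sep="\t", dtype=str)
        return frozenset(zip(df["mirna_id"], df["target_id"]))

    return TargetTables(_read(mir_to_lnc_path), _read(mir_to_mrna_path))


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    annotations: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                annotations[parts[0]] = [g for g in parts[2:] if g]
    return annotations


def read_ppi(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})


def config_from_mapping(mapping: dict) -> SimulationConfig:
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigurationError(f"unknown simulation fields: {sorted(unknown)}")
    if "ppi_score_range" in mapping:
        mapping = dict(mapping)
        mapping["ppi_score_range"] = tuple(mapping["ppi_score_range"])
    return SimulationConfig(**mapping)
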