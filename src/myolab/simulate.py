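"""Synthetic two-group bead-array studies with a cell-mixture ground truth.

The generator emulates the structure of a labouring vs non-labouring bulk
myometrium experiment in which part of the between-group signal is
*compositional*: leukocytes infiltrate the tissue at labour and dilute the
smooth-muscle transcript pool, so muscle-restricted genes appear
down-regulated and leukocyte-restricted genes appear up-regulated even when
no cell changes its transcription.  Each synthetic sample ``s`` carries a
leukocyte fraction ``f_s`` drawn from a group-specific Beta distribution;
a gene ``g`` with pure-tissue intensities ``mu_muscle_g`` / ``mu_leukocyte_g``
and a multiplicative transcriptional labour effect ``beta_g`` has true signal

    t_gs = [(1 - f_s) * mu_muscle_g + f_s * mu_leukocyte_g]
           * (beta_g if s is labouring else 1)

observed through per-sample scale factors, multiplicative log-normal noise
and an additive Gaussian background floor (negative-control probes receive
background only)::

    y_gs = b_gs + scale_s * t_gs * exp(eps_gs)

Everything is deterministic given the design seed, and every study ships a
truth table (per-gene expected apparent direction, split into compositional
and transcriptional parts, plus the per-sample fractions f_s) so downstream
stages can be scored without real data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ConfigurationError,
    ExpressionMatrix,
    GROUP_LABOUR,
    GROUP_NONLABOUR,
    require_positive,
)

GENE_CLASSES = (
    "muscle_specific",
    "leukocyte_specific",
    "labour_induced",
    "labour_repressed",
    "housekeeping",
    "negative_control",
)

#: Backgrounds are truncated below at this intensity so observations stay positive.
_TRUNC_FLOOR = 1e-3


@dataclass(frozen=True)
class Gene:
    """One catalog entry: identity, compartment intensities and labour effect."""

    gene_id: str
    gene_class: str
    mu_muscle: float
    mu_leukocyte: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ConfigurationError(
                f"parameter 'gene_class' must be one of {GENE_CLASSES}, got {self.gene_class!r}"
            )
        require_positive("mu_muscle", self.mu_muscle, strict=False)
        require_positive("mu_leukocyte", self.mu_leukocyte, strict=False)
        require_positive("beta", self.beta)
        if self.gene_class == "muscle_specific" and not (
            self.mu_muscle > 0 and self.mu_leukocyte == 0
        ):
            raise ConfigurationError(
                f"muscle_specific gene {self.gene_id} must have mu_muscle > 0 and mu_leukocyte = 0"
            )
        if self.gene_class == "leukocyte_specific" and not (
            self.mu_leukocyte > 0 and self.mu_muscle == 0
        ):
            raise ConfigurationError(
                f"leukocyte_specific gene {self.gene_id} must have mu_leukocyte > 0 and mu_muscle = 0"
            )
        if self.gene_class == "negative_control" and not (
            self.mu_muscle == 0 and self.mu_leukocyte == 0 and self.beta == 1
        ):
            raise ConfigurationError(
                f"negative_control gene {self.gene_id} must have zero expression and beta = 1"
            )
        if self.beta != 1 and self.gene_class not in ("labour_induced", "labour_repressed"):
            raise ConfigurationError(
                f"gene {self.gene_id}: beta != 1 only allowed for labour_induced/labour_repressed"
            )
        if self.gene_class == "labour_induced" and not self.beta > 1:
            raise ConfigurationError(f"labour_induced gene {self.gene_id} needs beta > 1")
        if self.gene_class == "labour_repressed" and not self.beta < 1:
            raise ConfigurationError(f"labour_repressed gene {self.gene_id} needs beta < 1")


@dataclass(frozen=True)
class MixtureParams:
    """Composition and noise model for one study.

    ``f_nonlabour`` / ``f_labour`` are (alpha, beta) shape pairs of the Beta
    distributions the leukocyte fraction is drawn from.  Defaults give mean
    fractions 0.05 (non-labouring) and 0.30 (labouring) with a deliberately
    wider labouring spread, reproducing the greater heterogeneity of
    labouring samples.  ``background_mean`` is chosen so the median
    negative-control intensity lands near the conventional detection floor
    of 100 intensity units.
    """

    f_nonlabour: tuple[float, float] | float = (2.0, 38.0)
    f_labour: tuple[float, float] | float = (3.0, 7.0)
    noise_sd_log: float = 0.3
    background_mean: float = 100.0
    background_sd: float = 15.0
    scale_spread: float = 0.05
    n_chips: int = 4

    def __post_init__(self) -> None:
        for name in ("f_nonlabour", "f_labour"):
            spec = getattr(self, name)
            if isinstance(spec, (int, float)):  # degenerate point mass
                if not 0.0 <= spec < 1.0:
                    raise ConfigurationError(
                        f"parameter {name!r} point mass must be in [0, 1), got {spec}"
                    )
                continue
            a, b = spec
            require_positive(f"{name}[0]", a)
            require_positive(f"{name}[1]", b)
        require_positive("noise_sd_log", self.noise_sd_log, strict=False)
        require_positive("background_mean", self.background_mean)
        require_positive("background_sd", self.background_sd, strict=False)
        require_positive("scale_spread", self.scale_spread, strict=False)
        if self.n_chips < 1:
            raise ConfigurationError(f"parameter 'n_chips' must be >= 1, got {self.n_chips}")

    def mean_fraction(self, group: str) -> float:
        spec = self.f_labour if group == GROUP_LABOUR else self.f_nonlabour
        if isinstance(spec, (int, float)):
            return float(spec)
        a, b = spec
        return a / (a + b)

    def draw_fraction(self, group: str, rng: np.random.Generator, size: int) -> np.ndarray:
        spec = self.f_labour if group == GROUP_LABOUR else self.f_nonlabour
        if isinstance(spec, (int, float)):
            return np.full(size, float(spec))
        a, b = spec
        return rng.beta(a, b, size=size)


@dataclass(frozen=True)
class StudyDesign:
    """Sample-level design: group sizes, null covariate generators, seed."""

    n_labour: int = 22
    n_nonlabour: int = 26
    induced_fraction: float = 0.5
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_labour < 2 or self.n_nonlabour < 2:
            raise ConfigurationError(
                f"group sizes must be >= 2, got {self.n_labour}/{self.n_nonlabour}"
            )
        if not 0.0 <= self.induced_fraction <= 1.0:
            raise ConfigurationError(
                f"parameter 'induced_fraction' must be in [0, 1], got {self.induced_fraction}"
            )


@dataclass
class SyntheticStudy:
    """A generated study: raw intensities, metadata and the ground truth."""

    expression: ExpressionMatrix
    metadata: pd.DataFrame
    truth: pd.DataFrame  # per-gene: class, beta, directions
    leukocyte_fraction: pd.Series  # per-sample f_s
    label: str = "synthetic"

    def write(self, outdir: str | Path, prefix: str = "study") -> dict[str, Path]:
        """Write the TSV bundle (matrix, controls, metadata, truth, fractions)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "matrix": outdir / f"{prefix}_expression.tsv",
            "controls": outdir / f"{prefix}_controls.tsv",
            "metadata": outdir / f"{prefix}_metadata.tsv",
            "truth": outdir / f"{prefix}_truth.tsv",
            "fractions": outdir / f"{prefix}_leukocyte_fraction.tsv",
        }
        self.expression.to_tsv(paths["matrix"], paths["controls"])
        self.metadata.rename_axis("sample_id").reset_index().to_csv(
            paths["metadata"], sep="\t", index=False
        )
        self.truth.rename_axis("gene_id").reset_index().to_csv(
            paths["truth"], sep="\t", index=False
        )
        self.leukocyte_fraction.rename("f_s").rename_axis("sample_id").reset_index().to_csv(
            paths["fractions"], sep="\t", index=False
        )
        return paths


# ---------------------------------------------------------------------------
# catalog construction
# ---------------------------------------------------------------------------

DEFAULT_CLASS_SIZES = {
    "muscle_specific": 200,
    "leukocyte_specific": 200,
    "labour_induced": 100,
    "labour_repressed": 50,
    "housekeeping": 1400,
    "negative_control": 100,
}


def default_catalog(
    class_sizes: dict[str, int] | None = None,
    beta_induced: float = 2.0,
    beta_repressed: float = 0.5,
    seed: int = 0,
) -> list[Gene]:
    """Build the default gene catalog.

    Marker classes (muscle/leukocyte-specific) get high, tight intensity
    draws — cell-type marker panels are strongly expressed in their own
    compartment — while housekeeping genes span a broad lognormal so a
    realistic tail falls below the detection floor.  Labour-effect genes are
    expressed equally in both compartments so their apparent direction is
    purely transcriptional.
    """
    sizes = dict(DEFAULT_CLASS_SIZES)
    if class_sizes:
        sizes.update(class_sizes)
    rng = np.random.default_rng(seed)
    genes: list[Gene] = []

    def lognorm(n: int, median: float, sd_log: float) -> np.ndarray:
        return median * np.exp(rng.normal(0.0, sd_log, size=n))

    n = sizes.get("muscle_specific", 0)
    for i, mu in enumerate(lognorm(n, 1000.0, 0.6)):
        genes.append(Gene(f"MUSC{i:04d}", "muscle_specific", float(mu), 0.0))
    n = sizes.get("leukocyte_specific", 0)
    for i, mu in enumerate(lognorm(n, 1000.0, 0.6)):
        genes.append(Gene(f"LEUK{i:04d}", "leukocyte_specific", 0.0, float(mu)))
    n = sizes.get("labour_induced", 0)
    for i, mu in enumerate(lognorm(n, 500.0, 0.6)):
        genes.append(Gene(f"LIND{i:04d}", "labour_induced", float(mu), float(mu), beta_induced))
    n = sizes.get("labour_repressed", 0)
    for i, mu in enumerate(lognorm(n, 500.0, 0.6)):
        genes.append(Gene(f"LREP{i:04d}", "labour_repressed", float(mu), float(mu), beta_repressed))
    n = sizes.get("housekeeping", 0)
    for i, mu in enumerate(lognorm(n, 500.0, 1.0)):
        genes.append(Gene(f"HKPG{i:04d}", "housekeeping", float(mu), float(mu)))
    n = sizes.get("negative_control", 0)
    for i in range(n):
        genes.append(Gene(f"NEGC{i:04d}", "negative_control", 0.0, 0.0))
    return genes


def catalog_frame(catalog: list[Gene]) -> pd.DataFrame:
    """Catalog as a DataFrame indexed by gene_id."""
    if not catalog:
        raise ConfigurationError("gene catalog is empty")
    df = pd.DataFrame([dataclasses.asdict(g) for g in catalog]).set_index("gene_id")
    if df.index.has_duplicates:
        raise ConfigurationError("duplicate gene ids in catalog")
    return df


# ---------------------------------------------------------------------------
# expected apparent direction (the truth object)
# ---------------------------------------------------------------------------

def expected_ratio(
    mu_muscle: np.ndarray,
    mu_leukocyte: np.ndarray,
    beta: np.ndarray,
    f_labour_mean: float,
    f_nonlabour_mean: float,
) -> np.ndarray:
    """Expected labour/non-labour signal ratio under the mixture model
    evaluated at the group-mean leukocyte fractions.  NaN where a gene is
    unexpressed in both compartments."""
    num = (1 - f_labour_mean) * mu_muscle + f_labour_mean * mu_leukocyte
    den = (1 - f_nonlabour_mean) * mu_muscle + f_nonlabour_mean * mu_leukocyte
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = beta * num / den
    ratio[(num == 0) & (den == 0)] = np.nan
    return ratio


def _direction(ratio: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
    # tolerance absorbs rounding in the mixture arithmetic when both
    # compartments carry identical intensities (true ratio exactly 1)
    out = np.full(ratio.shape, "none", dtype=object)
    out[ratio > 1 + rtol] = "up"
    out[ratio < 1 - rtol] = "down"
    return out


def build_truth(catalog_df: pd.DataFrame, mix: MixtureParams) -> pd.DataFrame:
    """Per-gene expected apparent directions, compositional and
    transcriptional components reported separately."""
    fl = mix.mean_fraction(GROUP_LABOUR)
    fn = mix.mean_fraction(GROUP_NONLABOUR)
    mu_m = catalog_df["mu_muscle"].to_numpy(float)
    mu_l = catalog_df["mu_leukocyte"].to_numpy(float)
    beta = catalog_df["beta"].to_numpy(float)
    comp_ratio = expected_ratio(mu_m, mu_l, np.ones_like(beta), fl, fn)
    total_ratio = expected_ratio(mu_m, mu_l, beta, fl, fn)
    return pd.DataFrame(
        {
            "gene_class": catalog_df["gene_class"],
            "beta": catalog_df["beta"],
            "expected_compositional_direction": _direction(comp_ratio),
            "expected_transcriptional_direction": _direction(beta / 1.0),
            "expected_total_direction": _direction(total_ratio),
            "expected_ratio": total_ratio,
        },
        index=catalog_df.index,
    )


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size) -> np.ndarray:
    """Normal draws truncated below at a small positive constant (rejection-free:
    values below the floor are clamped — sd/mean ratios here make that rare)."""
    if sd == 0:
        return np.full(size, max(mean, _TRUNC_FLOOR))
    draws = rng.normal(mean, sd, size=size)
    return np.maximum(draws, _TRUNC_FLOOR)


def _make_metadata(design: StudyDesign, rng: np.random.Generator, n_chips: int) -> pd.DataFrame:
    n = design.n_labour + design.n_nonlabour
    sample_ids = [f"{design.label}_L{i:02d}" for i in range(design.n_labour)] + [
        f"{design.label}_N{i:02d}" for i in range(design.n_nonlabour)
    ]
    group = [GROUP_LABOUR] * design.n_labour + [GROUP_NONLABOUR] * design.n_nonlabour
    # Null covariates: identically distributed in both groups by construction.
    parity = rng.choice([0, 0, 1, 1, 2, 3], size=n)
    bmi = np.round(rng.normal(28.0, 4.5, size=n), 1)
    maternal_age = np.round(rng.normal(32.0, 5.0, size=n), 0).astype(int)
    gestational_weeks = np.round(rng.normal(39.5, 1.2, size=n), 1)
    induction = np.array(["none"] * n, dtype=object)
    n_induced = int(round(design.induced_fraction * design.n_labour))
    induced_idx = rng.choice(design.n_labour, size=n_induced, replace=False)
    treatments = rng.choice(["prostaglandins", "oxytocin", "both"], size=n_induced, p=[0.3, 0.6, 0.1])
    induction[induced_idx] = treatments
    chip = rng.integers(1, n_chips + 1, size=n)  # recorded, zero effect by default
    return pd.DataFrame(
        {
            "group": group,
            "parity": parity,
            "bmi": bmi,
            "maternal_age": maternal_age,
            "gestational_weeks": gestational_weeks,
            "induction": induction,
            "chip": chip,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


def generate_study(
    catalog: list[Gene],
    mix: MixtureParams | None = None,
    design: StudyDesign | None = None,
) -> SyntheticStudy:
    """Generate one two-group study under the mixture model.

    Deterministic given ``design.seed``: the same seed and inputs produce a
    bit-identical study.
    """
    mix = mix or MixtureParams()
    design = design or StudyDesign()
    cat = catalog_frame(catalog)
    rng = np.random.default_rng(design.seed)

    metadata = _make_metadata(design, rng, mix.n_chips)
    n_samples = len(metadata)
    is_labour = (metadata["group"] == GROUP_LABOUR).to_numpy()

    # per-sample leukocyte fraction
    f = np.empty(n_samples)
    f[is_labour] = mix.draw_fraction(GROUP_LABOUR, rng, int(is_labour.sum()))
    f[~is_labour] = mix.draw_fraction(GROUP_NONLABOUR, rng, int((~is_labour).sum()))

    scale = np.exp(rng.normal(0.0, mix.scale_spread, size=n_samples))

    mu_m = cat["mu_muscle"].to_numpy(float)[:, None]
    mu_l = cat["mu_leukocyte"].to_numpy(float)[:, None]
    beta = cat["beta"].to_numpy(float)[:, None]
    effect = np.where(is_labour[None, :], beta, 1.0)
    t = ((1 - f)[None, :] * mu_m + f[None, :] * mu_l) * effect

    eps = rng.normal(0.0, mix.noise_sd_log, size=t.shape) if mix.noise_sd_log > 0 else 0.0
    background = _truncated_normal(rng, mix.background_mean, mix.background_sd, t.shape)
    y = background + scale[None, :] * t * np.exp(eps)

    values = pd.DataFrame(y, index=cat.index.rename("probe_id"), columns=metadata.index)
    is_control = pd.Series(
        (cat["gene_class"] == "negative_control").to_numpy(), index=values.index
    )
    annotation = pd.DataFrame(
        {"gene_symbol": cat.index, "gene_class": cat["gene_class"].to_numpy()},
        index=values.index,
    )
    expr = ExpressionMatrix(values=values, is_control=is_control, annotation=annotation)
    truth = build_truth(cat, mix)
    fractions = pd.Series(f, index=metadata.index, name="f_s")
    return SyntheticStudy(
        expression=expr,
        metadata=metadata,
        truth=truth,
        leukocyte_fraction=fractions,
        label=design.label,
    )


def generate_multistudy(
    designs: list[StudyDesign],
    shared_gene_fraction: float = 0.5,
    attenuation: list[float] | None = None,
    seed: int = 0,
    catalog: list[Gene] | None = None,
    mix: MixtureParams | None = None,
) -> list[SyntheticStudy]:
    """Generate several studies with partially overlapping probe complements.

    A shared core of ``round(shared_gene_fraction * G)`` biological genes is
    present on every platform; the remaining genes appear on each platform
    independently with probability 0.5, so the cross-study intersection is
    approximately the core.  Study ``i``'s transcriptional effects are
    ``beta ** attenuation[i]``; negative-control probes are always present.
    """
    if len(designs) < 2:
        raise ConfigurationError("generate_multistudy needs >= 2 study designs")
    if not 0.0 < shared_gene_fraction <= 1.0:
        raise ConfigurationError(
            f"parameter 'shared_gene_fraction' must be in (0, 1], got {shared_gene_fraction}"
        )
    if attenuation is None:
        attenuation = [1.0] * len(designs)
    if len(attenuation) != len(designs):
        raise ConfigurationError(
            f"attenuation list length {len(attenuation)} != number of studies {len(designs)}"
        )
    catalog = catalog if catalog is not None else default_catalog(seed=seed)
    mix = mix or MixtureParams()
    rng = np.random.default_rng(seed)

    bio = [g for g in catalog if g.gene_class != "negative_control"]
    ctrl = [g for g in catalog if g.gene_class == "negative_control"]
    n_core = int(round(shared_gene_fraction * len(bio)))
    order = rng.permutation(len(bio))
    core_idx = set(order[:n_core].tolist())

    studies: list[SyntheticStudy] = []
    for i, (design, atten) in enumerate(zip(designs, attenuation)):
        keep: list[Gene] = []
        for j, g in enumerate(bio):
            if j in core_idx or (shared_gene_fraction < 1.0 and rng.random() < 0.5):
                keep.append(g)
        sub_catalog = []
        for g in keep:
            new_beta = float(g.beta**atten)
            if new_beta == 1.0 and g.gene_class in ("labour_induced", "labour_repressed"):
                # attenuated to null: reclassify so catalog invariants hold
                g = replace(g, gene_class="housekeeping", beta=1.0)
            else:
                g = replace(g, beta=new_beta)
            sub_catalog.append(g)
        sub_catalog.extend(ctrl)
        study_seed = int(rng.integers(0, 2**31 - 1))
        study_design = replace(design, seed=study_seed, label=design.label or f"study{i}")
        studies.append(generate_study(sub_catalog, mix, study_design))
    return studies
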