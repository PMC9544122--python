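"""Synthetic breeding-design data with known ground truth.

Emulates the study system end to end so every downstream stage can be
tested without any external data: a captive colony bred in cages of
three females to one male over two seasons, split-clutch assignment of
offspring to thermal treatments, dummy sires for wild-conceived
clutches, latent traits with additive genetic, maternal, cage and
residual variance components, and rendered grey-scale swatch images
whose appearance encodes the latent brightness, contrast and pattern
elongation of each animal.

Default design parameters are tuned to reproduce the study's totals
(about 179 phenotyped offspring from about 37 dams in about 30
parental and 41 offspring cages across 2 seasons).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .animal_model import (
    FIXED_EFFECTS,
    VARIANCE_COMPONENTS,
    fixed_effects_matrix,
    inbreeding_coefficients,
    topological_order,
    _parent_indices,
)

__all__ = [
    "BreedingDesignConfig",
    "TraitTruth",
    "SimulationTruth",
    "RenderParams",
    "simulate_pedigree",
    "drop_breeding_values",
    "simulate_records",
    "render_swatch",
    "render_params_for_record",
    "write_dataset",
]

TRAITS = ("brightness", "elongation", "contrast")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BreedingDesignConfig:
    """Breeding-design knobs; defaults approximate the study totals."""

    n_parental_cages: int = 15          # cages per season (3F : 1M each)
    females_per_cage: int = 3
    n_seasons: int = 2
    clutches_per_dam_per_season: int = 1
    offspring_per_clutch: tuple[int, int] = (2, 5)
    p_wild_conceived: float = 0.15      # clutch gets a unique dummy sire
    p_dam_repaired: float = 0.06        # dam's cage sire replaced in season 2
    p_dam_breeds: float = 0.58          # per-season breeding probability
    offspring_cage_capacity: tuple[int, int] = (3, 6)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_parental_cages", "females_per_cage", "n_seasons",
                     "clutches_per_dam_per_season"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("p_wild_conceived", "p_dam_repaired", "p_dam_breeds"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.offspring_per_clutch
        if lo < 1 or hi < lo:
            raise ValueError("offspring_per_clutch must be a valid range >= 1")
        lo, hi = self.offspring_cage_capacity
        if lo < 1 or hi > 8 or hi < lo:
            raise ValueError("offspring_cage_capacity must lie within 1..8")


@dataclass(frozen=True)
class TraitTruth:
    """True generative parameters for one trait.

    ``beta`` maps fixed-effect names (see ``FIXED_EFFECTS``) to their
    true values; unlisted effects are zero.  The five variances follow
    the animal-model decomposition; ``h2_true`` is their additive
    fraction.
    """

    beta: dict[str, float]
    sigma2_A: float
    sigma2_dam: float
    sigma2_pcage: float
    sigma2_ocage: float
    sigma2_R: float

    def __post_init__(self) -> None:
        bad = set(self.beta) - set(FIXED_EFFECTS)
        if bad:
            raise ValueError(f"unknown fixed-effect names: {sorted(bad)}")
        for name in VARIANCE_COMPONENTS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.total_variance > 0 and not 0.0 <= self.h2_true <= 1.0:
            raise ValueError("h2_true outside [0, 1]")

    @property
    def total_variance(self) -> float:
        return sum(getattr(self, n) for n in VARIANCE_COMPONENTS)

    @property
    def h2_true(self) -> float:
        tot = self.total_variance
        return self.sigma2_A / tot if tot > 0 else 0.0

    @classmethod
    def from_h2(
        cls,
        h2: float,
        total: float = 1.0,
        dam_frac: float = 0.10,
        pcage_frac: float = 0.05,
        ocage_frac: float = 0.10,
        beta: dict[str, float] | None = None,
    ) -> "TraitTruth":
        """Build a truth with a target heritability and total variance."""
        resid = 1.0 - h2 - dam_frac - pcage_frac - ocage_frac
        if resid < 0:
            raise ValueError("variance fractions exceed 1")
        return cls(
            beta=beta or {"intercept": 0.0},
            sigma2_A=h2 * total,
            sigma2_dam=dam_frac * total,
            sigma2_pcage=pcage_frac * total,
            sigma2_ocage=ocage_frac * total,
            sigma2_R=resid * total,
        )


@dataclass(frozen=True)
class SimulationTruth:
    """Per-trait generative truth for the three colouration metrics."""

    traits: dict[str, TraitTruth]

    def __post_init__(self) -> None:
        bad = set(self.traits) - set(TRAITS)
        if bad:
            raise ValueError(f"unknown traits: {sorted(bad)}")

    @classmethod
    def study_like(cls) -> "SimulationTruth":
        """Truth values emulating the study's reported effect sizes.

        Intercepts, year and age coefficients follow the reported
        coefficient table; heritabilities are set near the reported
        posterior modes (0.16 / 0.18 / 0.23) with modest maternal and
        cage components; total phenotypic variances are chosen to give
        realistic trait scales (brightness and contrast live in [0, 1],
        elongation is a ratio near 1).
        """
        return cls(
            traits={
                "brightness": TraitTruth.from_h2(
                    0.16, total=0.0025,
                    beta={"intercept": 0.3085, "year": -0.0345, "age_days": 0.0017},
                ),
                "elongation": TraitTruth.from_h2(
                    0.18, total=0.09,
                    beta={"intercept": 1.05, "year": 0.0026, "age_days": 0.0014},
                ),
                "contrast": TraitTruth.from_h2(
                    0.23, total=0.0064,
                    beta={"intercept": 0.35, "year": -0.0386, "age_days": 0.0011},
                ),
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {t: asdict(v) | {"h2_true": v.h2_true} for t, v in self.traits.items()},
            indent=2, sort_keys=True,
        )


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

def simulate_pedigree(config: BreedingDesignConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the breeding design; returns (pedigree, covariates).

    Founders (wild-caught dams and sires plus dummy sires for
    wild-conceived clutches) have unknown parents.  Every offspring has
    one dam and one sire; clutches are split across the two offspring
    treatments; covariates carry sex, year, age at photograph,
    treatments, dam, parental cage and offspring cage.
    """
    rng = np.random.default_rng(config.seed)
    n_dams = config.n_parental_cages * config.females_per_cage
    dams = [f"D{i + 1:03d}" for i in range(n_dams)]
    sires = [f"M{i + 1:03d}" for i in range(config.n_parental_cages)]

    # stable dam groups of size females_per_cage, one sire per group
    groups = [
        dams[c * config.females_per_cage : (c + 1) * config.females_per_cage]
        for c in range(config.n_parental_cages)
    ]
    group_sire = {c: sires[c] for c in range(config.n_parental_cages)}

    ped_rows: list[tuple[str, str, str]] = [(d, "", "") for d in dams]
    ped_rows += [(s, "", "") for s in sires]
    cov_rows: list[dict] = []
    n_dummy = 0
    n_extra_sires = 0
    off_counter = 0

    for season in range(config.n_seasons):
        year = 2015 + season
        # re-pair a fraction of cages in later seasons (sperm-storage /
        # re-housing uncertainty in the real colony)
        if season > 0:
            for c in range(config.n_parental_cages):
                if rng.random() < config.p_dam_repaired:
                    n_extra_sires += 1
                    new_sire = f"M{config.n_parental_cages + n_extra_sires:03d}"
                    ped_rows.append((new_sire, "", ""))
                    group_sire[c] = new_sire
        # balanced parental treatments over cages, reshuffled each season
        trt = np.array(["long-bask", "short-bask"])[
            rng.permutation(config.n_parental_cages) % 2
        ]
        season_clutches: list[dict] = []
        for c in range(config.n_parental_cages):
            pcage = f"PC{season + 1}-{c + 1:02d}"
            for dam in groups[c]:
                for _ in range(config.clutches_per_dam_per_season):
                    if rng.random() >= config.p_dam_breeds:
                        continue
                    lo, hi = config.offspring_per_clutch
                    size = int(rng.integers(lo, hi + 1))
                    if rng.random() < config.p_wild_conceived:
                        n_dummy += 1
                        sire = f"DUMMY{n_dummy:03d}"
                        ped_rows.append((sire, "", ""))
                    else:
                        sire = group_sire[c]
                    season_clutches.append(
                        {"dam": dam, "sire": sire, "size": size,
                         "pcage": pcage, "ptrt": trt[c]}
                    )

        # offspring records with split-clutch treatment assignment
        season_offspring: list[dict] = []
        for clutch in season_clutches:
            half = clutch["size"] // 2
            assign = ["long-bask"] * half + ["short-bask"] * (clutch["size"] - half)
            if rng.random() < 0.5:
                assign = assign[::-1]
            assign = [assign[i] for i in rng.permutation(clutch["size"])]
            for otrt in assign:
                off_counter += 1
                oid = f"O{off_counter:04d}"
                ped_rows.append((oid, clutch["sire"], clutch["dam"]))
                season_offspring.append(
                    {
                        "id": oid,
                        "sex": "male" if rng.random() < 0.5 else "female",
                        "year": year,
                        "age_days": int(rng.integers(6, 63)),
                        "offspring_treatment": otrt,
                        "parental_treatment": clutch["ptrt"],
                        "dam": clutch["dam"],
                        "parental_cage": clutch["pcage"],
                    }
                )

        # group hatchlings into offspring cages within season x treatment
        for otrt in ("long-bask", "short-bask"):
            members = [o for o in season_offspring if o["offspring_treatment"] == otrt]
            order = rng.permutation(len(members))
            i, cage_no = 0, 0
            lo, hi = config.offspring_cage_capacity
            while i < len(members):
                cage_no += 1
                cap = int(rng.integers(lo, hi + 1))
                tag = "L" if otrt == "long-bask" else "S"
                for j in order[i : i + cap]:
                    members[j]["offspring_cage"] = f"OC{season + 1}{tag}-{cage_no:02d}"
                i += cap
        cov_rows.extend(season_offspring)

    if not cov_rows:
        raise ValueError(
            "configuration produced zero offspring; increase cage counts, "
            "breeding probability or clutch sizes"
        )
    pedigree = pd.DataFrame(ped_rows, columns=["id", "sire", "dam"])
    covariates = pd.DataFrame(cov_rows)[
        ["id", "sex", "year", "age_days", "offspring_treatment",
         "parental_treatment", "dam", "parental_cage", "offspring_cage"]
    ]
    return pedigree, covariates


# ---------------------------------------------------------------------------
# gene dropping and phenotype simulation
# ---------------------------------------------------------------------------

def drop_breeding_values(
    pedigree: pd.DataFrame, sigma2_A: float, seed: int = 0
) -> pd.Series:
    """Simulate additive genetic values down the pedigree (gene dropping).

    Founders draw from Normal(0, sigma2_A); each non-founder is the
    mean of its parents' values plus a Mendelian-sampling deviation
    with variance ``(sigma2_A / 2) (1 - (F_sire + F_dam) / 2)``.  Over
    replicates the values have covariance ``A sigma2_A`` without ever
    building or factorising the dense relationship matrix.
    """
    if sigma2_A < 0:
        raise ValueError("sigma2_A must be >= 0")
    ids, sire, dam = _parent_indices(pedigree)
    order = topological_order(pedigree)
    F = inbreeding_coefficients(pedigree).to_numpy()
    rng = np.random.default_rng(seed)
    a = np.zeros(len(ids))
    for i in order:
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            a[i] = rng.normal(0.0, np.sqrt(sigma2_A))
        elif s >= 0 and d >= 0:
            v = 0.5 * sigma2_A * (1.0 - 0.5 * (F[s] + F[d]))
            a[i] = 0.5 * (a[s] + a[d]) + rng.normal(0.0, np.sqrt(v))
        else:
            p = s if s >= 0 else d
            v = sigma2_A * (0.75 - 0.25 * F[p])
            a[i] = 0.5 * a[p] + rng.normal(0.0, np.sqrt(v))
    return pd.Series(a, index=ids, name="breeding_value")


def simulate_records(
    pedigree: pd.DataFrame,
    covariates: pd.DataFrame,
    truth: SimulationTruth,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate phenotypes: y = X beta + a + dam + pcage + ocage + e.

    Each trait draws its own breeding values, iid dam / parental-cage /
    offspring-cage effects and residuals from the trait's true
    variances; traits are generated independently of each other.
    """
    required = ["id", "sex", "year", "age_days", "offspring_treatment",
                "parental_treatment", "dam", "parental_cage", "offspring_cage"]
    na_mask = covariates.reindex(columns=required).isna()
    if na_mask.to_numpy().any():
        bad = covariates.loc[na_mask.any(axis=1), "id"].tolist()
        raise ValueError(f"records with missing covariates: {bad[:10]}")

    X = fixed_effects_matrix(covariates)
    ss = np.random.SeedSequence(seed)
    out = covariates.copy()
    for trait, child in zip(TRAITS, ss.spawn(len(TRAITS))):
        tt = truth.traits[trait]
        sub = child.spawn(2)
        a = drop_breeding_values(pedigree, tt.sigma2_A, seed=sub[0])
        rng = np.random.default_rng(sub[1])
        beta = np.array([tt.beta.get(name, 0.0) for name in FIXED_EFFECTS])
        y = X @ beta + a.loc[covariates["id"].astype(str)].to_numpy()
        for col, s2 in (
            ("dam", tt.sigma2_dam),
            ("parental_cage", tt.sigma2_pcage),
            ("offspring_cage", tt.sigma2_ocage),
        ):
            levels = covariates[col].astype(str)
            eff = {lv: rng.normal(0.0, np.sqrt(s2)) for lv in sorted(levels.unique())}
            y = y + levels.map(eff).to_numpy()
        y = y + rng.normal(0.0, np.sqrt(tt.sigma2_R), size=len(covariates))
        out[trait] = y
    return out


# ---------------------------------------------------------------------------
# swatch rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderParams:
    """Appearance targets for one rendered swatch.

    ``anisotropy`` is the ratio of the longitudinal (down-the-body,
    vertical) to the transverse correlation length of the underlying
    random field: values above 1 produce lengthwise stripes and hence
    measured elongation above 1.  ``class_gap`` is the brightness
    difference between the brightest and darkest colour class, i.e. the
    target contrast; ``mean_brightness`` the target pixel-mean
    brightness.
    """

    mean_brightness: float = 0.4
    class_gap: float = 0.4
    anisotropy: float = 1.0
    n_classes: int = 3
    image_height: int = 120
    image_width: int = 80
    noise_sd: float = 2.0
    base_scale: float = 4.0   # geometric-mean correlation scale, pixels
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.n_classes <= 5):
            raise ValueError("n_classes must lie in 2..5")
        if self.anisotropy <= 0:
            raise ValueError("anisotropy must be positive")
        lo = self.mean_brightness - self.class_gap / 2.0
        hi = self.mean_brightness + self.class_gap / 2.0
        if lo < 0.0 or hi > 1.0:
            raise ValueError(
                f"infeasible brightness/gap: class brightness range [{lo:.3f}, "
                f"{hi:.3f}] leaves [0, 1]"
            )
        if self.image_height < 8 or self.image_width < 8:
            raise ValueError("image must be at least 8 x 8 pixels")


def render_swatch(params: RenderParams) -> np.ndarray:
    """Render a grey-scale swatch with known appearance targets.

    An anisotropic Gaussian random field (white noise smoothed with a
    separable Gaussian kernel, periodic boundaries) is thresholded at
    equal-share quantiles into ``n_classes`` classes.  Class greys are
    evenly spaced so the brightest-minus-darkest class brightness
    equals ``class_gap`` and the pixel-mean brightness equals
    ``mean_brightness``; iid channel noise is added and clipped.
    """
    rng = np.random.default_rng(params.seed)
    field_ = rng.standard_normal((params.image_height, params.image_width))
    s = params.base_scale
    sig_long = s * np.sqrt(params.anisotropy)     # axis 0: down the body
    sig_trans = s / np.sqrt(params.anisotropy)    # axis 1: across the body
    field_ = gaussian_filter(field_, sigma=(sig_long, sig_trans), mode="wrap")

    k = params.n_classes
    qs = np.quantile(field_, np.linspace(0, 1, k + 1)[1:-1])
    labels = np.digitize(field_, qs)  # 0..k-1, low field value = 0
    # evenly spaced greys centred on mean_brightness
    greys = params.mean_brightness + params.class_gap * (
        np.linspace(0, 1, k) - 0.5
    )
    img = greys[labels] * 255.0
    img = img[:, :, None] + rng.normal(0.0, params.noise_sd, size=img.shape + (3,))
    return np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)


def render_params_for_record(
    brightness: float, elongation: float, contrast: float,
    n_classes: int = 3, seed: int = 0,
    image_height: int = 120, image_width: int = 80,
) -> RenderParams:
    """Map latent trait values to feasible rendering targets.

    Latent contrast and brightness are clipped so the class-grey range
    stays inside [0, 1]; latent elongation is used directly as the
    field anisotropy (clipped to [1/6, 6]).
    """
    gap = float(np.clip(contrast, 0.05, 0.9))
    mb = float(np.clip(brightness, gap / 2 + 0.01, 1.0 - gap / 2 - 0.01))
    aniso = float(np.clip(elongation, 1.0 / 6.0, 6.0))
    return RenderParams(
        mean_brightness=mb, class_gap=gap, anisotropy=aniso,
        n_classes=n_classes, seed=seed,
        image_height=image_height, image_width=image_width,
    )


# ---------------------------------------------------------------------------
# dataset output
# ---------------------------------------------------------------------------

def write_dataset(
    outdir: str | Path,
    pedigree: pd.DataFrame,
    phenotypes: pd.DataFrame,
    truth: SimulationTruth | None = None,
    render: bool = False,
    image_seed: int = 0,
) -> Path:
    """Write pedigree.csv, phenotypes.csv, truth.json and optional PNGs.

    Pedigree columns are ``id, sire, dam`` with an empty field for an
    unknown parent; phenotype columns are the covariate schema plus the
    three trait columns.  With ``render=True`` one PNG per phenotyped
    individual is written under ``swatches/``, named ``<id>.png``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pedigree.to_csv(outdir / "pedigree.csv", index=False)
    phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
    if truth is not None:
        (outdir / "truth.json").write_text(truth.to_json())
    if render:
        from PIL import Image

        ss = np.random.SeedSequence(image_seed)
        seeds = ss.generate_state(len(phenotypes))
        img_dir = outdir / "swatches"
        img_dir.mkdir(exist_ok=True)
        for (_, row), s in zip(phenotypes.iterrows(), seeds):
            params = render_params_for_record(
                row["brightness"], row["elongation"], row["contrast"],
                seed=int(s) % (2**31),
            )
            Image.fromarray(render_swatch(params)).save(img_dir / f"{row['id']}.png")
    return outdir
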