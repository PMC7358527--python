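"""Synthetic field-study generator with retained ground truth.

Emulates a five-treatment, six-month, triplicate-plot soil sampling design
(two agricultural rotations, two early plant successional treatments, and
one unreplicated mid-successional forest site) and the measurements the
analysis pipeline consumes:

* viral/bacterial enumeration counts (multiplicative lognormal noise,
  log-linear dependence on soil organic carbon, seasonal variability of
  viral abundance scaling with organic carbon),
* mitomycin-C induction assays from a latent lysogen fraction and burst
  size, with optional growth of non-induced cells during the incubation
  (the mechanism that produces unreasonably low calculated burst sizes),
* triplicate T-RFLP peak profiles from hierarchical Dirichlet communities
  (treatment cores, seasonal drift, plot heterogeneity) with fragment-size
  jitter and peak dropout,
* binary RAPD band profiles per (month, site) whose month-to-month band
  turnover differs between free and induced viral assemblages,
* soil edaphic tables (moisture, organic C, total N, C:N, P, pH).

Every generator is a pure function of (parameters, seed); latent truth is
recorded for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .fingerprint import BandProfile
from .induction import InductionAssay
from .trflp import PeakProfile

__all__ = [
    "GeneratorParams",
    "SyntheticStudy",
    "generate_study",
    "generate_induction_assay",
    "generate_trflp_replicates",
    "generate_band_profiles",
]

DEFAULT_TREATMENTS = ("T1", "T4", "T7", "T8", "SF2")
DEFAULT_MONTHS = ("May", "June", "July", "September", "October", "November")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray | float:
    """Multiplicative lognormal noise with mean exactly 1 and the given CV."""
    if cv < 0:
        raise ValueError(f"coefficient of variation must be >= 0, got {cv!r}")
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


@dataclass(frozen=True)
class GeneratorParams:
    """Study-design and noise parameters of the synthetic generator.

    Defaults encode the emulated design: five land treatments sampled over
    six months (May through November) in triplicate plots, except the forest
    site which has a single plot.  Abundance scales are typical of temperate
    surface soils (~5e7 cells/g, VBR ~ 5), the assumed burst size is 20
    viruses per lysed cell, and organic carbon increases from the tilled
    agricultural soils toward the forest.
    """

    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    months: tuple[str, ...] = DEFAULT_MONTHS
    plots_per_treatment: tuple[int, ...] = (3, 3, 3, 3, 1)
    # abundances
    mean_bacterial_abundance: float = 5e7  # cells g^-1 (lognormal median)
    mean_vbr: float = 5.0
    count_cv: float = 0.25
    abundance_c_slope: float = 0.5  # d ln(abundance) per % organic C
    seasonal_va_sd_per_c: float = 0.15  # SD of ln viral abundance per % organic C
    # induction
    lysogen_fraction: tuple[float, ...] = (0.04, 0.03, 0.02, 0.025, 0.02)
    burst_size: float = 20.0
    noninduced_growth: float = 1.2
    # VLP background of the washed-cell control tube, per cell: the assay
    # works on Nycodenz-purified cells resuspended in autoclaved extract, so
    # the un-induced control carries far fewer viruses than bulk soil
    induction_background_vbr: float = 0.25
    # edaphics
    organic_c_by_treatment: tuple[float, ...] = (0.9, 1.1, 1.3, 1.6, 2.5)  # % by mass
    # community structure
    community_size: int = 30
    treatment_divergence: float = 0.6
    seasonal_drift: float = 0.2
    plot_heterogeneity: float = 0.1
    # T-RFLP
    total_fluorescence: float = 50_000.0
    trflp_replicates: int = 3
    trflp_noise_cv: float = 0.1
    trflp_dropout: float = 0.02
    size_jitter_sd: float = 0.15  # nt
    # RAPD fingerprints
    band_pool_size: int = 60
    band_core_density: float = 0.5
    band_treatment_divergence_free: float = 0.15
    band_treatment_divergence_induced: float = 0.35
    band_turnover_free: float = 0.05
    band_turnover_induced: float = 0.10
    band_plot_heterogeneity: float = 0.05

    def __post_init__(self) -> None:
        k = len(self.treatments)
        for name in ("plots_per_treatment", "lysogen_fraction", "organic_c_by_treatment"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have one entry per treatment ({k})")
        if min(self.plots_per_treatment) < 1:
            raise ValueError("every treatment needs at least one plot")
        if len(self.months) < 1:
            raise ValueError("need at least one month")
        for f_name in ("count_cv", "trflp_noise_cv", "trflp_dropout",
                       "band_core_density", "band_turnover_free",
                       "band_turnover_induced", "band_plot_heterogeneity"):
            v = getattr(self, f_name)
            if v < 0 or (f_name != "count_cv" and f_name != "trflp_noise_cv" and v > 1):
                raise ValueError(f"{f_name} out of range: {v!r}")
        if any(not 0 <= f <= 1 for f in self.lysogen_fraction):
            raise ValueError("lysogen fractions must lie in [0, 1]")
        if self.burst_size <= 0:
            raise ValueError("burst size must be positive")
        if self.noninduced_growth < 1:
            raise ValueError("noninduced growth factor must be >= 1")
        if self.band_pool_size < 1:
            raise ValueError("band pool must be non-empty")


@dataclass(frozen=True)
class SyntheticStudy:
    """Generated study tables plus the latent truth that produced them."""

    enumeration: pd.DataFrame
    induction: pd.DataFrame
    peaks: pd.DataFrame
    bands: pd.DataFrame
    edaphics: pd.DataFrame
    truth: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "enumeration": self.enumeration,
            "induction": self.induction,
            "peaks": self.peaks,
            "bands": self.bands,
            "edaphics": self.edaphics,
        }


def generate_induction_assay(
    true_if: float,
    burst: float,
    bc: float,
    growth: float = 1.0,
    cv: float = 0.0,
    seed: int | np.random.Generator = 0,
    vc: float | None = None,
) -> InductionAssay:
    """One induction assay from the latent lysogeny model.

    Lysed cells ``L = true_if * bc``; before noise ``Vm = Vc + burst * L``,
    ``Bm = (bc - L) * growth`` and ``Bc = bc * growth`` (growth acts equally
    on both tubes, which is what erodes the Bc - Bm lysis signal).  Each of
    the four counts then receives independent mean-1 lognormal noise with
    coefficient of variation `cv`.
    """
    if not 0 <= true_if <= 1:
        raise ValueError(f"true inducible fraction must lie in [0, 1], got {true_if!r}")
    if bc <= 0:
        raise ValueError("starting bacterial abundance must be positive")
    if cv < 0:
        raise ValueError(f"cv must be >= 0, got {cv!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if vc is None:
        vc = 0.25 * bc  # washed-cell tube: low background VLP count
    lysed = true_if * bc
    latent = np.array([vc, vc + burst * lysed, bc * growth, (bc - lysed) * growth])
    noisy = latent * _lognormal_factor(rng, cv, size=4)
    return InductionAssay(vc=noisy[0], vm=noisy[1], bc=noisy[2], bm=noisy[3])


def generate_trflp_replicates(
    community: np.ndarray,
    taxon_sizes: np.ndarray,
    total_fluorescence: float = 50_000.0,
    n_reps: int = 3,
    size_jitter_sd: float = 0.15,
    dropout: float = 0.0,
    noise_cv: float = 0.1,
    seed: int | np.random.Generator = 0,
    min_separation: float = 1.0,
    sample_id: str = "sample",
) -> list[PeakProfile]:
    """Replicate T-RFLP profiles of one community.

    Peak heights are proportional to relative abundance times the trace
    total, with mean-1 lognormal noise; fragment sizes are jittered
    N(0, size_jitter_sd^2); peaks drop out independently at rate `dropout`.
    Taxon sizes must be separated by more than `min_separation` (twice the
    binning tolerance) so jittered peaks cannot collide across taxa.
    """
    community = np.asarray(community, dtype=float)
    taxon_sizes = np.asarray(taxon_sizes, dtype=float)
    if community.shape != taxon_sizes.shape:
        raise ValueError("community and taxon_sizes must align")
    if not math.isclose(community.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("community relative abundances must sum to 1")
    if np.any(np.diff(np.sort(taxon_sizes)) <= min_separation):
        raise ValueError(
            f"taxon sizes must be separated by more than {min_separation} nt"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reps = []
    for r in range(n_reps):
        heights = community * total_fluorescence * _lognormal_factor(
            rng, noise_cv, size=community.size
        )
        sizes = taxon_sizes + (
            rng.normal(0.0, size_jitter_sd, size=taxon_sizes.size)
            if size_jitter_sd > 0
            else 0.0
        )
        keep = (heights > 0) & (rng.random(community.size) >= dropout)
        reps.append(
            PeakProfile(
                sample_id=f"{sample_id}/rep{r + 1}",
                sizes=sizes[keep],
                heights=heights[keep],
            )
        )
    return reps


def generate_band_profiles(
    treatments: tuple[str, ...],
    months: tuple[str, ...],
    pool_size: int = 60,
    turnover: float = 0.05,
    plot_heterogeneity: float = 0.0,
    core_density: float = 0.5,
    treatment_divergence: float = 0.15,
    seed: int | np.random.Generator = 0,
    cores: dict[str, np.ndarray] | None = None,
) -> list[BandProfile]:
    """Binary band fingerprints per (month, site) with monthly band turnover.

    A global core band set is drawn from a shared pool of fragment positions
    (log-spaced 100-1000 bp); each treatment's core flips positions at rate
    `treatment_divergence` (land-use structure with moderate between-site
    dissimilarity).  Month to month every pool position flips (a band
    appears or disappears) with probability `turnover`, and a final
    plot-level flip at rate `plot_heterogeneity` emulates within-plot
    heterogeneity.  Pass `cores` (treatment -> boolean pool mask) to control
    treatment band sets explicitly.
    """
    if pool_size < 1:
        raise ValueError("band pool must be non-empty")
    if not 0 <= turnover <= 1:
        raise ValueError(f"turnover must lie in [0, 1], got {turnover!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = np.geomspace(100.0, 1000.0, pool_size)
    global_core = rng.random(pool_size) < core_density
    if not global_core.any():
        global_core[rng.integers(pool_size)] = True
    profiles = []
    for t_idx, treatment in enumerate(treatments):
        if cores is not None:
            state = np.asarray(cores[treatment], dtype=bool).copy()
        else:
            state = global_core ^ (rng.random(pool_size) < treatment_divergence)
            if not state.any():
                state[rng.integers(pool_size)] = True
        for month in months:
            flips = rng.random(pool_size) < turnover
            state = state ^ flips
            lane = state.copy()
            if plot_heterogeneity > 0:
                lane ^= rng.random(pool_size) < plot_heterogeneity
            if not lane.any():  # a lane with no bands cannot enter Dice
                lane[rng.integers(pool_size)] = True
            profiles.append(
                BandProfile(label=f"{month}|{treatment}", bands=pool[lane])
            )
    return profiles


def _hierarchical_community(
    rng: np.random.Generator, base: np.ndarray, spread: float
) -> np.ndarray:
    """Dirichlet resample of `base` with relative spread `spread` (0 = copy)."""
    if spread <= 0:
        return base.copy()
    alpha = np.maximum(base * (base.size / spread), 1e-6)
    draw = rng.dirichlet(alpha)
    return draw / draw.sum()


def generate_study(params: GeneratorParams, seed: int) -> SyntheticStudy:
    """Generate a complete synthetic study (all five tables plus truth).

    The latent chain: treatment-level organic C sets a log-linear shift of
    bacterial and viral abundance; viral abundance additionally receives a
    monthly deviation whose SD is proportional to organic C (so seasonal
    variability of viral abundance rises with carbon); induction assays are
    driven by the per-treatment lysogen fraction and the shared burst size;
    communities follow a treatment/month/plot Dirichlet hierarchy; band
    profiles evolve by monthly turnover at different rates for free and
    induced assemblages.
    """
    rng = np.random.default_rng(seed)
    p = params
    c_ref = float(np.mean(p.organic_c_by_treatment))
    base_community = rng.dirichlet(np.full(p.community_size, 5.0))
    taxon_sizes = 60.0 + 3.0 * np.arange(p.community_size)

    enum_rows, induction_rows, edaphic_rows, peak_rows = [], [], [], []
    communities: dict[str, list[float]] = {}
    month_effects: dict[tuple[str, str], float] = {}

    for t_idx, treatment in enumerate(p.treatments):
        c_t = p.organic_c_by_treatment[t_idx]
        true_if = p.lysogen_fraction[t_idx]
        treat_comm = _hierarchical_community(rng, base_community, p.treatment_divergence)
        ln_ba = math.log(p.mean_bacterial_abundance) + p.abundance_c_slope * (c_t - c_ref)
        ln_va = ln_ba + math.log(p.mean_vbr)
        for month in p.months:
            month_effect = rng.normal(0.0, p.seasonal_va_sd_per_c * c_t) if (
                p.seasonal_va_sd_per_c > 0
            ) else 0.0
            month_effects[(treatment, month)] = month_effect
            month_comm = _hierarchical_community(rng, treat_comm, p.seasonal_drift)
            for plot in range(1, p.plots_per_treatment[t_idx] + 1):
                sample_id = f"{treatment}-{month}-p{plot}"
                ba_latent = math.exp(ln_ba)
                va_latent = math.exp(ln_va + month_effect)
                ba = ba_latent * float(_lognormal_factor(rng, p.count_cv))
                va = va_latent * float(_lognormal_factor(rng, p.count_cv))
                enum_rows.append(
                    {
                        "sample_id": sample_id,
                        "treatment": treatment,
                        "month": month,
                        "plot": plot,
                        "viral_abundance": va,
                        "bacterial_abundance": ba,
                    }
                )
                assay = generate_induction_assay(
                    true_if=true_if,
                    burst=p.burst_size,
                    bc=ba_latent,
                    growth=p.noninduced_growth,
                    cv=p.count_cv,
                    seed=rng,
                    vc=p.induction_background_vbr * ba_latent,
                )
                induction_rows.append(
                    {
                        "sample_id": sample_id,
                        "treatment": treatment,
                        "month": month,
                        "plot": plot,
                        "v_control": assay.vc,
                        "v_mitc": assay.vm,
                        "b_control": assay.bc,
                        "b_mitc": assay.bm,
                    }
                )
                organic_c = c_t * float(_lognormal_factor(rng, 0.05))
                total_n = organic_c / (11.0 + rng.normal(0.0, 0.5))
                edaphic_rows.append(
                    {
                        "sample_id": sample_id,
                        "treatment": treatment,
                        "month": month,
                        "plot": plot,
                        "moisture": 0.12 + 0.04 * c_t + rng.normal(0.0, 0.01),
                        "organic_c": organic_c,
                        "total_n": total_n,
                        "cn_ratio": organic_c / total_n,
                        "phosphorus": 30.0 + rng.normal(0.0, 3.0),
                        "ph": 6.5 + rng.normal(0.0, 0.15),
                    }
                )
                plot_comm = _hierarchical_community(rng, month_comm, p.plot_heterogeneity)
                communities[sample_id] = plot_comm.tolist()
                for rep in generate_trflp_replicates(
                    plot_comm,
                    taxon_sizes,
                    total_fluorescence=p.total_fluorescence,
                    n_reps=p.trflp_replicates,
                    size_jitter_sd=p.size_jitter_sd,
                    dropout=p.trflp_dropout,
                    noise_cv=p.trflp_noise_cv,
                    seed=rng,
                    sample_id=sample_id,
                ):
                    rep_no = int(rep.sample_id.rsplit("rep", 1)[1])
                    for size, height in zip(rep.sizes, rep.heights):
                        peak_rows.append(
                            {
                                "sample_id": sample_id,
                                "treatment": treatment,
                                "month": month,
                                "plot": plot,
                                "replicate": rep_no,
                                "size": size,
                                "height": height,
                            }
                        )

    band_rows = []
    for assemblage, turnover, divergence in (
        ("free", p.band_turnover_free, p.band_treatment_divergence_free),
        ("induced", p.band_turnover_induced, p.band_treatment_divergence_induced),
    ):
        for prof in generate_band_profiles(
            p.treatments,
            p.months,
            pool_size=p.band_pool_size,
            turnover=turnover,
            plot_heterogeneity=p.band_plot_heterogeneity,
            core_density=p.band_core_density,
            treatment_divergence=divergence,
            seed=rng,
        ):
            month, treatment = prof.label.split("|")
            for pos in prof.bands:
                band_rows.append(
                    {
                        "assemblage": assemblage,
                        "label": prof.label,
                        "treatment": treatment,
                        "month": month,
                        "position": pos,
                    }
                )

    truth = {
        "params": asdict(p),
        "seed": seed,
        "lysogen_fraction": dict(zip(p.treatments, p.lysogen_fraction)),
        "burst_size": p.burst_size,
        "taxon_sizes": taxon_sizes.tolist(),
        "communities": communities,
        "viral_month_effects": {
            f"{t}|{m}": e for (t, m), e in month_effects.items()
        },
    }
    return SyntheticStudy(
        enumeration=pd.DataFrame(enum_rows),
        induction=pd.DataFrame(induction_rows),
        peaks=pd.DataFrame(peak_rows),
        bands=pd.DataFrame(band_rows),
        edaphics=pd.DataFrame(edaphic_rows),
        truth=truth,
    )
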