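"""Synthetic urine-like 1H NMR cohorts with known ground truth.

Real rodent urine spectra are dominated by a few dozen small-molecule
resonances (creatinine, citrate, hippurate, 2-oxoglutarate, TMAO, ...)
riding on a smooth baseline, with three nuisance processes that any
urinary-metabolomics pipeline has to survive:

* multiplicative dilution — urine concentration varies several-fold
  between voids, modelled here as a per-sample log-normal factor;
* chemical-shift jitter — pH- and ionic-strength-driven displacement of
  whole multiplets, modelled per sample and per metabolite;
* additive thermal noise and a slowly varying baseline.

The generator plants group × period fold-changes on chosen metabolites
so that every downstream stage (alignment, PQN, OPLS-DA, univariate
z-scores, STOCSY) can be tested against an exact ground truth.  Line
shapes are Lorentzian, the standard model for solution-state 1H lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PPM_MIN = 0.5
PPM_MAX = 9.8

#: the six treatment arms of the study design this generator emulates:
#: normal control, healthy + herbal formula, thioacetamide model,
#: thioacetamide + formula, bile-duct ligation, ligation + formula.
GROUPS = ("NC", "HLD", "TAA", "THC", "BDL", "BHD")

#: urine collection periods with their hour ranges after treatment.
PERIOD_HOURS = {
    "T1": (0, 8),
    "T2": (8, 24),
    "T3": (24, 32),
    "T4": (32, 48),
    "T5": (48, 72),
    "T6": (72, 96),
    "T7": (96, 120),
    "T8": (120, 144),
}
PERIODS = tuple(PERIOD_HOURS)


@dataclass(frozen=True)
class Peak:
    """One multiplet: a center, line offsets around it, relative heights
    and a common full-width-at-half-maximum, all in ppm."""

    center: float
    offsets: tuple[float, ...] = (0.0,)
    heights: tuple[float, ...] = (1.0,)
    linewidth: float = 0.012

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.heights):
            raise ValueError("offsets and heights must have equal length")
        if any(h <= 0 for h in self.heights):
            raise ValueError("line heights must be > 0")
        if self.linewidth <= 0:
            raise ValueError("linewidth must be > 0")
        for off in self.offsets:
            c = self.center + off
            if not (PPM_MIN <= c <= PPM_MAX):
                raise ValueError(
                    f"line center {c:.3f} ppm outside [{PPM_MIN}, {PPM_MAX}]"
                )


@dataclass(frozen=True)
class MetaboliteSignature:
    """A named metabolite as a set of multiplets plus a base concentration
    in arbitrary units."""

    name: str
    peaks: tuple[Peak, ...]
    base_concentration: float

    def __post_init__(self) -> None:
        if self.base_concentration <= 0:
            raise ValueError("base_concentration must be > 0")
        if not self.peaks:
            raise ValueError("a signature needs at least one peak")


@dataclass(frozen=True)
class EffectSpec:
    """A planted group effect: multiplicative fold-change on one
    metabolite, per collection period, in the named groups."""

    metabolite: str
    groups: tuple[str, ...]
    fold_changes: dict[str, float]  # period label -> fold

    def __post_init__(self) -> None:
        for p, f in self.fold_changes.items():
            if p not in PERIODS:
                raise ValueError(f"unknown period label {p!r}")
            if f <= 0:
                raise ValueError("fold-changes must be > 0")

    @property
    def direction(self) -> str:
        logs = [math.log(f) for f in self.fold_changes.values()]
        return "up" if sum(logs) >= 0 else "down"


@dataclass(frozen=True)
class NoiseModel:
    """Nuisance-process parameters.

    ``concentration_rsd`` is the log-scale SD of per-sample,
    per-metabolite biological variation; without it PQN would strip all
    within-group variance and every comparison would be degenerate.
    """

    additive_sd: float = 0.02
    baseline_amplitude: float = 0.05
    shift_jitter_sd: float = 0.002
    dilution_log_mean: float = 0.0
    dilution_log_sd: float = 0.3
    concentration_rsd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("additive_sd", "baseline_amplitude", "shift_jitter_sd",
                     "dilution_log_sd", "concentration_rsd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CohortDesign:
    """Group × subject × period layout of a cohort."""

    groups: tuple[str, ...] = GROUPS
    n_subjects: int = 6
    periods: tuple[str, ...] = PERIODS

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("design needs at least one group")
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        bad = set(self.periods) - set(PERIODS)
        if bad:
            raise ValueError(f"unknown periods: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.groups) * self.n_subjects * len(self.periods)


# ---------------------------------------------------------------------------
# default metabolite library
# ---------------------------------------------------------------------------

# (name, [(center, offsets, heights, linewidth), ...], base concentration)
# ppm positions follow standard urinary 1H assignments; concentrations are
# plausible relative urinary abundances, not calibrated to any study.
_LIBRARY_TABLE: list[tuple[str, list[tuple], float]] = [
    ("creatinine", [(3.05, (0.0,), (1.0,), 0.010), (4.06, (0.0,), (0.6,), 0.010)], 10.0),
    ("citrate", [(2.54, (-0.008, 0.008), (1.0, 1.0), 0.012),
                 (2.66, (-0.008, 0.008), (1.0, 1.0), 0.012)], 6.0),
    ("hippurate", [(3.97, (-0.004, 0.004), (1.0, 1.0), 0.010),
                   (7.55, (-0.006, 0.0, 0.006), (0.5, 1.0, 0.5), 0.010),
                   (7.64, (-0.006, 0.0, 0.006), (0.5, 1.0, 0.5), 0.010),
                   (7.84, (-0.004, 0.004), (1.0, 1.0), 0.010)], 5.0),
    ("2-oxoglutarate", [(2.44, (-0.006, 0.0, 0.006), (0.5, 1.0, 0.5), 0.012),
                        (3.01, (-0.006, 0.0, 0.006), (0.5, 1.0, 0.5), 0.012)], 4.0),
    ("succinate", [(2.41, (0.0,), (1.0,), 0.010)], 2.0),
    ("lactate", [(1.33, (-0.004, 0.004), (1.0, 1.0), 0.010),
                 (4.12, (-0.006, -0.002, 0.002, 0.006), (0.3, 1.0, 1.0, 0.3), 0.010)], 3.0),
    ("alanine", [(1.48, (-0.004, 0.004), (1.0, 1.0), 0.010)], 2.0),
    ("acetate", [(1.92, (0.0,), (1.0,), 0.010)], 1.5),
    ("taurine", [(3.27, (-0.005, 0.0, 0.005), (0.5, 1.0, 0.5), 0.012),
                 (3.43, (-0.005, 0.0, 0.005), (0.5, 1.0, 0.5), 0.012)], 3.0),
    ("TMAO", [(3.26, (0.0,), (1.0,), 0.010)], 4.0),
    ("glycine", [(3.57, (0.0,), (1.0,), 0.010)], 2.5),
    ("creatine", [(3.04, (0.0,), (1.0,), 0.010), (3.93, (0.0,), (0.7,), 0.010)], 2.0),
    ("dimethylamine", [(2.72, (0.0,), (1.0,), 0.010)], 1.5),
    ("glutamate", [(2.08, (-0.01, 0.0, 0.01), (0.6, 1.0, 0.6), 0.014),
                   (2.35, (-0.01, 0.0, 0.01), (0.6, 1.0, 0.6), 0.014),
                   (3.76, (0.0,), (0.5,), 0.012)], 2.0),
    ("glutarate", [(1.78, (-0.008, 0.0, 0.008), (0.6, 1.0, 0.6), 0.013),
                   (2.18, (-0.006, 0.006), (1.0, 1.0), 0.012)], 1.5),
    ("N-acetylglutamate", [(2.02, (0.0,), (1.0,), 0.011)], 1.5),
    ("valine", [(0.99, (-0.004, 0.004), (1.0, 1.0), 0.010),
                (1.04, (-0.004, 0.004), (1.0, 1.0), 0.010)], 1.0),
    ("leucine", [(0.96, (-0.005, 0.0, 0.005), (0.6, 1.0, 0.6), 0.010)], 1.0),
    ("isoleucine", [(0.94, (-0.004, 0.004), (1.0, 1.0), 0.010),
                    (1.01, (-0.004, 0.004), (1.0, 1.0), 0.010)], 0.8),
    ("3-hydroxybutyrate", [(1.20, (-0.004, 0.004), (1.0, 1.0), 0.010),
                           (2.31, (-0.006, 0.006), (0.8, 0.8), 0.012)], 1.0),
    ("formate", [(8.46, (0.0,), (1.0,), 0.010)], 0.8),
    ("fumarate", [(6.52, (0.0,), (1.0,), 0.010)], 0.5),
    ("phenylalanine", [(7.33, (-0.004, 0.004), (1.0, 1.0), 0.011),
                       (7.38, (-0.004, 0.004), (0.8, 0.8), 0.011),
                       (7.43, (-0.004, 0.004), (1.0, 1.0), 0.011)], 1.0),
    ("tyrosine", [(6.90, (-0.004, 0.004), (1.0, 1.0), 0.011),
                  (7.19, (-0.004, 0.004), (1.0, 1.0), 0.011)], 0.8),
    ("histidine", [(7.07, (0.0,), (1.0,), 0.011), (7.79, (0.0,), (1.0,), 0.011)], 0.7),
    ("benzoate", [(7.48, (-0.006, 0.0, 0.006), (0.5, 1.0, 0.5), 0.011),
                  (7.87, (-0.004, 0.004), (1.0, 1.0), 0.011)], 1.0),
    ("3-indoxylsulfate", [(7.20, (-0.006, 0.0, 0.006), (0.5, 1.0, 0.5), 0.011),
                          (7.28, (-0.006, 0.0, 0.006), (0.5, 1.0, 0.5), 0.011),
                          (7.50, (-0.004, 0.004), (1.0, 1.0), 0.011),
                          (7.70, (-0.004, 0.004), (1.0, 1.0), 0.011)], 1.2),
    ("trigonelline", [(8.08, (-0.006, 0.0, 0.006), (0.5, 1.0, 0.5), 0.011),
                      (8.84, (-0.004, 0.004), (1.0, 1.0), 0.011),
                      (9.12, (0.0,), (1.0,), 0.011)], 1.0),
    ("1-methylnicotinamide", [(8.90, (0.0,), (1.0,), 0.011),
                              (8.97, (0.0,), (0.9,), 0.011),
                              (9.28, (0.0,), (1.0,), 0.011)], 0.5),
    ("allantoin", [(5.39, (0.0,), (1.0,), 0.012)], 2.0),
    ("urea", [(5.78, (0.0,), (1.0,), 0.080)], 20.0),
    ("guanidoacetate", [(3.80, (0.0,), (1.0,), 0.011)], 1.5),
    ("trimethylamine", [(2.88, (0.0,), (1.0,), 0.010)], 0.6),
]


def build_default_library(seed: int = 0) -> list[MetaboliteSignature]:
    """Build the default urinary metabolite library.

    Peak positions and multiplet structures are fixed; the seed applies a
    mild deterministic log-normal jitter (~10 %) to base concentrations so
    different seeds give different but realistic abundance patterns.
    """
    rng = np.random.default_rng(seed)
    library = []
    for name, peak_rows, base in _LIBRARY_TABLE:
        peaks = tuple(
            Peak(center=c, offsets=tuple(offs), heights=tuple(hts), linewidth=lw)
            for c, offs, hts, lw in peak_rows
        )
        conc = base * float(rng.lognormal(mean=0.0, sigma=0.10))
        library.append(MetaboliteSignature(name=name, peaks=peaks,
                                           base_concentration=conc))
    return library


def default_effects() -> list[EffectSpec]:
    """Planted effects emulating the qualitative pattern of a
    hepatotoxin / cholestasis study: the model groups (TAA, BDL) shift a
    handful of metabolites, peaking mid-study; the treated groups
    (THC, BHD) show the same shifts attenuated; HLD shows a mild shift.
    """

    def profile(peak_fold: float, atten: float = 1.0) -> dict[str, float]:
        # effect grows to a mid-study peak (T3-T4) and partially resolves
        shape = {"T1": 0.3, "T2": 0.7, "T3": 1.0, "T4": 1.0,
                 "T5": 0.8, "T6": 0.6, "T7": 0.45, "T8": 0.3}
        return {p: math.exp(atten * s * math.log(peak_fold))
                for p, s in shape.items()}

    effects: list[EffectSpec] = []
    model_pattern = {
        "citrate": 0.5, "2-oxoglutarate": 0.5, "hippurate": 0.45,
        "glutamate": 2.2, "taurine": 1.9, "glycine": 1.8,
        "trigonelline": 0.55, "phenylalanine": 0.6,
    }
    for metab, fold in model_pattern.items():
        effects.append(EffectSpec(metab, ("TAA", "BDL"), profile(fold)))
        effects.append(EffectSpec(metab, ("THC", "BHD"), profile(fold, atten=0.45)))
    for metab, fold in {"glutamate": 1.5, "succinate": 1.4,
                        "hippurate": 0.7, "citrate": 0.75}.items():
        effects.append(EffectSpec(metab, ("HLD",), profile(fold)))
    return effects


# ---------------------------------------------------------------------------
# spectrum synthesis
# ---------------------------------------------------------------------------


def make_ppm_grid(step: float = 0.001,
                  low: float = PPM_MIN, high: float = PPM_MAX) -> np.ndarray:
    """Uniform ascending ppm axis covering [low, high]."""
    if step <= 0:
        raise ValueError("step must be > 0")
    n = int(round((high - low) / step)) + 1
    return low + step * np.arange(n)


def _render_signature(ppm: np.ndarray, sig: MetaboliteSignature,
                      concentration: float, shift: float) -> np.ndarray:
    """Lorentzian rendering of one metabolite at a given concentration,
    with the whole signature displaced by `shift` ppm."""
    out = np.zeros_like(ppm)
    for peak in sig.peaks:
        hw = peak.linewidth / 2.0
        for off, h in zip(peak.offsets, peak.heights):
            c = peak.center + off + shift
            out += h * hw * hw / ((ppm - c) ** 2 + hw * hw)
    return concentration * out


def _smooth_baseline(ppm: np.ndarray, amplitude: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Slowly varying baseline: three low-frequency cosines with random
    phases, scaled to the requested amplitude."""
    if amplitude == 0:
        return np.zeros_like(ppm)
    x = (ppm - ppm[0]) / (ppm[-1] - ppm[0])
    base = np.zeros_like(ppm)
    for k in (1, 2, 3):
        phase = rng.uniform(0, 2 * np.pi)
        base += rng.uniform(0.3, 1.0) / k * np.cos(2 * np.pi * k * x + phase)
    return amplitude * base


def generate_cohort(
    design: CohortDesign,
    library: list[MetaboliteSignature],
    effects: list[EffectSpec],
    noise: NoiseModel,
    ppm_step: float = 0.001,
):
    """Simulate one spectrum per (group, subject, period).

    Each spectrum is
    ``dilution × Σ_m fold·biovar·concentration_m · Lorentzians_m(ppm + jitter_m)
    + baseline + additive noise``.

    Returns ``(SpectralMatrix, metadata, truth)`` where metadata has one
    row per sample (sample_id, group, subject, period, dilution) and truth
    lists every planted (metabolite, group, period, fold_change).
    """
    from .preprocess import SpectralMatrix  # local import avoids a cycle

    lib_names = {s.name for s in library}
    for eff in effects:
        if eff.metabolite not in lib_names:
            raise ValueError(
                f"effect refers to metabolite {eff.metabolite!r} "
                "absent from the library"
            )

    ppm = make_ppm_grid(ppm_step)
    rng = np.random.default_rng(noise.seed)

    # fold lookup: (metabolite, group, period) -> product of planted folds
    fold: dict[tuple[str, str, str], float] = {}
    truth_rows = []
    for eff in effects:
        for g in eff.groups:
            for p, f in eff.fold_changes.items():
                key = (eff.metabolite, g, p)
                fold[key] = fold.get(key, 1.0) * f
    for (m, g, p), f in sorted(fold.items()):
        truth_rows.append({"metabolite": m, "group": g, "period": p,
                           "fold_change": f})

    n_samples = design.n_samples
    X = np.empty((n_samples, ppm.size))
    meta_rows = []
    i = 0
    for group in design.groups:
        for subj in range(1, design.n_subjects + 1):
            for period in design.periods:
                sample_id = f"{group}_s{subj:02d}_{period}"
                spectrum = np.zeros_like(ppm)
                for sig in library:
                    conc = sig.base_concentration
                    conc *= fold.get((sig.name, group, period), 1.0)
                    if noise.concentration_rsd > 0:
                        conc *= rng.lognormal(0.0, noise.concentration_rsd)
                    shift = (rng.normal(0.0, noise.shift_jitter_sd)
                             if noise.shift_jitter_sd > 0 else 0.0)
                    spectrum += _render_signature(ppm, sig, conc, shift)
                dilution = float(rng.lognormal(noise.dilution_log_mean,
                                               noise.dilution_log_sd))
                y = dilution * spectrum
                y += _smooth_baseline(ppm, noise.baseline_amplitude, rng)
                if noise.additive_sd > 0:
                    y += rng.normal(0.0, noise.additive_sd, size=ppm.size)
                X[i] = y
                meta_rows.append({"sample_id": sample_id, "group": group,
                                  "subject": f"{group}_s{subj:02d}",
                                  "period": period, "dilution": dilution})
                i += 1

    matrix = SpectralMatrix(ppm=ppm, data=X,
                            sample_ids=[r["sample_id"] for r in meta_rows])
    metadata = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(
        truth_rows, columns=["metabolite", "group", "period", "fold_change"]
    )
    return matrix, metadata, truth


def library_windows(library: list[MetaboliteSignature],
                    pad: float = 0.02) -> dict[str, list[tuple[float, float]]]:
    """ppm integration windows implied by a library: one closed interval
    per multiplet, padded by `pad` ppm, clipped to the analysis range."""
    windows: dict[str, list[tuple[float, float]]] = {}
    for sig in library:
        spans = []
        for peak in sig.peaks:
            lo = peak.center + min(peak.offsets) - peak.linewidth - pad
            hi = peak.center + max(peak.offsets) + peak.linewidth + pad
            spans.append((max(lo, PPM_MIN), min(hi, PPM_MAX)))
        spans.sort()
        merged = [spans[0]]
        for lo, hi in spans[1:]:  # multiplets of one metabolite may abut
            if lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
            else:
                merged.append((lo, hi))
        windows[sig.name] = merged
    return windows
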