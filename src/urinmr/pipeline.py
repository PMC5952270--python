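"""Orchestration: configuration, tabular I/O and the full analysis run.

A run executes preprocessing once, then per configured two-group
comparison an OPLS-DA fit with cross-validation / permutation / ROC
validation, then univariate profiling under the study's reference-group
mapping, and optional STOCSY drivers.  All randomness flows from the
single global seed (stage seeds are spawned from it), so rerunning with
the same config reproduces all numeric outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .preprocess import (SpectralMatrix, BinnedMatrix, standard_preprocess,
                         apply_scaling, center_and_pareto_scale,
                         WATER_UREA_PPM)
from .opls import ClassVector, fit_oplsda, predict, splot, trajectory, \
    training_scores
from .validate import validate_comparison, permutation_test
from .univariate import (MetaboliteWindowTable, integrate_metabolites,
                         relative_levels, zscore_table, significance_stars,
                         REFERENCE_MAPPING)
from .stocsy import run_stocsy
from . import plots

log = logging.getLogger("urinmr")

_AXIS_TOL = 1e-9


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------


def write_spectral_matrix(X: SpectralMatrix, path) -> str:
    """TSV with first column ppm (written descending, the display
    convention) and one column per sample."""
    df = pd.DataFrame(X.data.T[::-1], columns=X.sample_ids)
    df.insert(0, "ppm", X.ppm[::-1])
    df.to_csv(path, sep="\t", index=False)
    return str(path)


def read_spectral_matrix(path) -> SpectralMatrix:
    """Read a ppm × samples TSV; the axis may be written in either
    direction and is stored ascending.  The axis must be uniform within
    1e-9; duplicate sample ids and non-numeric cells are rejected with
    line numbers."""
    df = pd.read_csv(path, sep="\t")
    if "ppm" not in df.columns:
        raise ValueError(f"{path}: first column must be 'ppm'")
    ids = [c for c in df.columns if c != "ppm"]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sample ids")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(np.where(bad)[0][0]) + 2  # header is line 1
            raise ValueError(f"{path}: non-numeric cell in column "
                             f"{col!r} at line {line}")
        if df[col].isna().any():
            line = int(np.where(df[col].isna())[0][0]) + 2
            raise ValueError(f"{path}: missing value in column "
                             f"{col!r} at line {line}")
    ppm = df["ppm"].to_numpy(dtype=float)
    steps = np.diff(ppm)
    if np.all(steps < 0):
        pass  # SpectralMatrix reorders ascending
    elif not np.all(steps > 0):
        raise ValueError(f"{path}: ppm axis is not strictly monotone")
    if np.ptp(np.abs(steps)) > _AXIS_TOL:
        raise ValueError(f"{path}: ppm axis is not uniform within 1e-9")
    data = df[ids].to_numpy(dtype=float).T
    return SpectralMatrix(ppm=ppm, data=data, sample_ids=ids)


def write_metadata(metadata: pd.DataFrame, path) -> str:
    metadata.to_csv(path, sep="\t", index=False)
    return str(path)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "group", "subject", "period"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: metadata needs columns {sorted(need)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    return df


def read_windows(path) -> MetaboliteWindowTable:
    return MetaboliteWindowTable.read_tsv(path)


def check_consistency(X: SpectralMatrix, metadata: pd.DataFrame) -> None:
    """Every metadata sample must exist in the matrix and vice versa."""
    m_ids = set(metadata["sample_id"])
    x_ids = set(X.sample_ids)
    missing = sorted(m_ids - x_ids)
    if missing:
        raise ValueError(f"sample {missing[0]!r} in metadata is absent "
                         "from the spectral matrix")
    extra = sorted(x_ids - m_ids)
    if extra:
        raise ValueError(f"sample {extra[0]!r} in the spectral matrix has "
                         "no metadata row")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Comparison:
    group_a: str  # positive / case
    group_b: str  # negative / control
    projection_groups: tuple[str, ...] = ()

    def __post_init__(self):
        if self.group_a == self.group_b:
            raise ValueError("a comparison needs two distinct groups")

    @property
    def name(self) -> str:
        return f"{self.group_a}_vs_{self.group_b}"


#: the study's standard contrasts.
DEFAULT_COMPARISONS = (
    Comparison("HLD", "NC"),
    Comparison("TAA", "NC"),
    Comparison("THC", "TAA"),
    Comparison("BDL", "NC"),
    Comparison("BHD", "BDL"),
)


@dataclass
class AnalysisConfig:
    spectra_path: str
    metadata_path: str
    windows_path: str | None
    output_dir: str
    comparisons: tuple[Comparison, ...] = DEFAULT_COMPARISONS
    seed: int = 0
    # preprocess
    segment_ppm: float = 0.2
    max_shift_ppm: float = 0.02
    exclude: tuple[tuple[float, float], ...] = (WATER_UREA_PPM,)
    bin_range: tuple[float, float] = (0.5, 9.8)
    bin_width: float = 0.04
    pqn_reference: str = "median"
    # modelling / validation
    n_ortho: int = 1
    n_repeats: int = 50
    n_perm: int = 200
    perm_repeats: int = 5
    # univariate
    reference_mapping: dict = field(
        default_factory=lambda: {k: list(v)
                                 for k, v in REFERENCE_MAPPING.items()})
    zscore_clip: float = 3.0
    # stocsy
    stocsy_drivers: tuple[float, ...] = ()
    stocsy_threshold: float = 0.8

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Load from YAML (JSON is a subset of YAML and also accepted)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        comps = tuple(
            Comparison(c["group_a"], c["group_b"],
                       tuple(c.get("projection_groups", ())))
            for c in raw.pop("comparisons", [])
        ) or DEFAULT_COMPARISONS
        exclude = tuple(tuple(r) for r in raw.pop("exclude",
                                                  [list(WATER_UREA_PPM)]))
        bin_range = tuple(raw.pop("bin_range", (0.5, 9.8)))
        drivers = tuple(raw.pop("stocsy_drivers", ()))
        return cls(comparisons=comps, exclude=exclude, bin_range=bin_range,
                   stocsy_drivers=drivers, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["comparisons"] = [asdict(c) for c in self.comparisons]
        return d


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    validation: dict            # comparison name -> ValidationReport dict
    manifest: list[str]
    fingerprint: str
    config: dict
    log: list[str]

    def to_json(self, path) -> str:
        with open(path, "w") as fh:
            json.dump({"fingerprint": self.fingerprint,
                       "validation": self.validation,
                       "manifest": sorted(self.manifest),
                       "config": self.config,
                       "log": self.log}, fh, indent=2, sort_keys=True)
        return str(path)


def _subset(B: BinnedMatrix, ids: list[str]) -> BinnedMatrix:
    rows = [B.sample_ids.index(s) for s in ids]
    from dataclasses import replace
    return replace(B, data=B.data[rows], sample_ids=list(ids))


def run_pipeline(config: AnalysisConfig) -> RunReport:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    messages: list[str] = []

    def note(msg: str) -> None:
        log.info(msg)
        messages.append(msg)

    X = read_spectral_matrix(config.spectra_path)
    metadata = read_metadata(config.metadata_path)
    check_consistency(X, metadata)
    known = set(metadata["group"])
    for comp in config.comparisons:
        for g in (comp.group_a, comp.group_b, *comp.projection_groups):
            if g not in known:
                raise ValueError(f"comparison {comp.name}: unknown group {g!r}")

    seedseq = np.random.SeedSequence(config.seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2**31))
                   for name, s in zip(
                       ("validate", "stocsy"), seedseq.spawn(2))}

    # --- preprocessing, once -------------------------------------------------
    normalized, scaled = standard_preprocess(
        X, config.segment_ppm, config.max_shift_ppm, config.exclude,
        config.bin_range, config.bin_width, config.pqn_reference)
    note(f"preprocessed {normalized.n_samples} spectra into "
         f"{normalized.centers.size} bins")
    binned_path = out / "binned_normalized.tsv"
    bdf = pd.DataFrame(normalized.data, index=normalized.sample_ids,
                       columns=[f"{c:.3f}" for c in normalized.centers])
    bdf.rename_axis("sample_id").to_csv(binned_path, sep="\t")
    manifest.append(str(binned_path))

    meta_idx = metadata.set_index("sample_id")
    validation: dict[str, dict] = {}
    period_order = [p for p in
                    ("T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8")
                    if p in set(metadata["period"])]

    # --- per-comparison modelling -------------------------------------------
    for i, comp in enumerate(config.comparisons):
        sub_ids = [s for s in normalized.sample_ids
                   if meta_idx.loc[s, "group"] in (comp.group_a, comp.group_b)]
        B_norm = _subset(normalized, sub_ids)
        B_scaled = center_and_pareto_scale(B_norm)
        cv = ClassVector.from_labels(
            sub_ids, [meta_idx.loc[s, "group"] for s in sub_ids],
            positive_label=comp.group_a)
        try:
            model = fit_oplsda(B_scaled, cv, config.n_ortho)
            report = validate_comparison(
                B_norm, cv, config.n_ortho, config.n_repeats,
                config.n_perm, config.perm_repeats,
                seed=stage_seeds["validate"] + i)
        except Exception as exc:  # logged failure per contract
            note(f"comparison {comp.name} failed: {exc}")
            validation[comp.name] = {"error": str(exc)}
            continue
        validation[comp.name] = report.to_dict()
        note(f"{comp.name}: R2={report.r2:.3f} Q2={report.q2:.3f} "
             f"({report.label}) AUROC={report.auroc:.3f}")

        scores = training_scores(model)
        if comp.projection_groups:
            proj_ids = [s for s in normalized.sample_ids
                        if meta_idx.loc[s, "group"] in comp.projection_groups]
            B_proj = apply_scaling(_subset(normalized, proj_ids), B_scaled)
            scores = pd.concat([scores, predict(model, B_proj)],
                               ignore_index=True)

        prefix = out / comp.name
        scores.to_csv(f"{prefix}_scores.tsv", sep="\t", index=False)
        sp = splot(model)
        sp.to_csv(f"{prefix}_splot.tsv", sep="\t", index=False)
        with open(f"{prefix}_model.json", "w") as fh:
            json.dump(model.to_dict(), fh, indent=2)
        manifest += [f"{prefix}_scores.tsv", f"{prefix}_splot.tsv",
                     f"{prefix}_model.json"]
        manifest.append(plots.plot_scores(
            scores, metadata, f"{prefix}_scores.png", comp.name))
        traj_groups = (comp.group_a, comp.group_b, *comp.projection_groups)
        traj = trajectory(scores, metadata, traj_groups, period_order)
        traj.to_csv(f"{prefix}_trajectory.tsv", sep="\t", index=False)
        manifest.append(f"{prefix}_trajectory.tsv")
        manifest.append(plots.plot_trajectory(
            traj, f"{prefix}_trajectory.png", comp.name))
        manifest.append(plots.plot_loadings(
            sp, f"{prefix}_loadings.png", comp.name))
        manifest.append(plots.plot_splot(sp, f"{prefix}_splot.png", comp.name))
        if report.permutation is not None:
            manifest.append(plots.plot_permutation(
                report.permutation, f"{prefix}_permutation.png", comp.name))
        manifest.append(plots.plot_roc(report.roc, f"{prefix}_roc.png",
                                       comp.name))
        report.to_json(f"{prefix}_validation.json")
        manifest.append(f"{prefix}_validation.json")

    # --- all-group projection overview on the first successful model ---------
    if len(known) > 2 and config.comparisons:
        comp = config.comparisons[0]
        try:
            sub_ids = [s for s in normalized.sample_ids
                       if meta_idx.loc[s, "group"] in (comp.group_a,
                                                       comp.group_b)]
            B_norm = _subset(normalized, sub_ids)
            B_scaled = center_and_pareto_scale(B_norm)
            cv = ClassVector.from_labels(
                sub_ids, [meta_idx.loc[s, "group"] for s in sub_ids],
                positive_label=comp.group_a)
            model = fit_oplsda(B_scaled, cv, config.n_ortho)
            other = [s for s in normalized.sample_ids if s not in sub_ids]
            scores = pd.concat(
                [training_scores(model),
                 predict(model, apply_scaling(_subset(normalized, other),
                                              B_scaled))],
                ignore_index=True)
            manifest.append(plots.plot_scores(
                scores, metadata, out / "all_groups_projection.png",
                f"all groups projected on {comp.name}"))
        except Exception as exc:
            note(f"all-group projection skipped: {exc}")

    # --- univariate ----------------------------------------------------------
    if config.windows_path:
        windows = read_windows(config.windows_path)
        levels = integrate_metabolites(normalized, windows)
        levels.to_csv(out / "metabolite_levels.tsv", sep="\t")
        manifest.append(str(out / "metabolite_levels.tsv"))
        for ref, targets in config.reference_mapping.items():
            targets = [t for t in targets if t in known]
            if ref not in known or not targets:
                continue
            tables = [relative_levels(levels, metadata, t, ref)
                      for t in targets]
            rel = pd.concat(tables, ignore_index=True)
            rel.to_csv(out / f"relative_levels_vs_{ref}.tsv", sep="\t",
                       index=False)
            manifest.append(str(out / f"relative_levels_vs_{ref}.tsv"))
            for t, table in zip(targets, tables):
                z = zscore_table(table, config.zscore_clip, period_order)
                stars = significance_stars(table, period_order)
                zp = out / f"zscores_{t}_vs_{ref}.tsv"
                z.to_csv(zp, sep="\t")
                manifest.append(str(zp))
                manifest.append(plots.plot_zscore_heatmap(
                    z, out / f"zscores_{t}_vs_{ref}.png", stars,
                    config.zscore_clip, f"{t} vs {ref}"))
            note(f"univariate: {len(targets)} groups vs {ref}")

    # --- stocsy --------------------------------------------------------------
    for ppm in config.stocsy_drivers:
        res = run_stocsy(normalized, ppm, config.stocsy_threshold)
        sp_path = out / f"stocsy_{ppm:.3f}.tsv"
        res.to_frame().to_csv(sp_path, sep="\t", index=False)
        manifest.append(str(sp_path))
        manifest.append(plots.plot_stocsy(
            res, out / f"stocsy_{ppm:.3f}.png"))

    # --- report --------------------------------------------------------------
    cfg = config.to_dict()
    fingerprint = hashlib.sha256(
        (json.dumps(cfg, sort_keys=True) + __version__).encode()
    ).hexdigest()[:16]
    report = RunReport(validation=validation,
                       manifest=[str(m) for m in manifest],
                       fingerprint=f"urinmr-{__version__}-{fingerprint}",
                       config=cfg, log=messages)
    missing = [m for m in report.manifest if not Path(m).exists()]
    if missing:
        raise RuntimeError(f"manifest lists missing files: {missing}")
    report.to_json(out / "run_report.json")
    return report
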