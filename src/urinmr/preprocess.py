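"""Spectral preprocessing: alignment, region exclusion, binning,
probabilistic quotient normalization (PQN) and mean-centering with
Pareto scaling.

The stage order is fixed — align → exclude → bin → PQN → center/Pareto —
and each stage records itself in provenance flags and refuses to run out
of order.  Binning sums point intensities (conserving integrals), PQN
divides each sample by the median quotient against a reference spectrum
(removing multiplicative dilution), and Pareto scaling divides each
mean-centered variable by the square root of its standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

_AXIS_TOL = 1e-9


def _check_uniform(ppm: np.ndarray) -> float:
    steps = np.diff(ppm)
    if ppm.size < 2 or not np.all(steps > 0):
        raise ValueError("ppm axis must be strictly increasing")
    step = float(steps[0])
    if not np.allclose(steps, step, rtol=0, atol=_AXIS_TOL):
        raise ValueError("ppm axis must be uniform")
    return step


@dataclass
class SpectralMatrix:
    """Continuous spectra: ppm axis (stored ascending) × samples."""

    ppm: np.ndarray
    data: np.ndarray
    sample_ids: list[str]
    provenance: tuple[str, ...] = ()
    excluded: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.ppm.ndim != 1:
            raise ValueError("ppm axis must be one-dimensional")
        d = np.diff(self.ppm)
        if d.size and np.all(d < 0):  # descending input: reorder ascending
            self.ppm = self.ppm[::-1].copy()
            self.data = self.data[:, ::-1].copy()
        elif d.size and not np.all(d > 0):
            raise ValueError("ppm axis must be strictly monotone")
        if self.data.shape != (len(self.sample_ids), self.ppm.size):
            raise ValueError("data must be samples × points matching ids/axis")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class BinnedMatrix:
    """Samples × bins matrix with provenance flags.

    ``edges`` is an (n_bins, 2) array of half-open [low, high) intervals;
    bins need not be contiguous once excluded regions are dropped.
    ``original_sd`` / ``col_means`` hold the constants used by
    center/Pareto scaling so loadings can be back-scaled and new samples
    projected with the training parameters.
    """

    edges: np.ndarray
    centers: np.ndarray
    data: np.ndarray
    sample_ids: list[str]
    normalized: bool = False
    scaled: bool = False
    excluded: tuple[tuple[float, float], ...] = ()
    original_sd: np.ndarray | None = None
    col_means: np.ndarray | None = None
    zero_variance: np.ndarray | None = None
    pqn_reference: np.ndarray | None = None
    dilution_estimates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float).reshape(-1, 2)
        self.centers = np.asarray(self.centers, dtype=float)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape != (len(self.sample_ids), self.centers.size):
            raise ValueError("data must be samples × bins")
        order = self.edges[:, 0]
        if np.any(np.diff(order) <= 0):
            raise ValueError("bin edges must be ordered and non-overlapping")
        if np.any(self.edges[:-1, 1] > self.edges[1:, 0] + _AXIS_TOL):
            raise ValueError("bin intervals overlap")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "BinnedMatrix":
        return replace(self, data=self.data.copy())


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def _shift_segment(seg: np.ndarray, lag: int) -> np.ndarray:
    """Shift a 1-D segment by `lag` points, extending edge values."""
    if lag == 0:
        return seg.copy()
    out = np.empty_like(seg)
    if lag > 0:
        out[lag:] = seg[:-lag]
        out[:lag] = seg[0]
    else:
        out[:lag] = seg[-lag:]
        out[lag:] = seg[-1]
    return out


def align_spectra(
    X: SpectralMatrix,
    segment_ppm: float = 0.2,
    max_shift_ppm: float = 0.02,
    reference: str | int = "median",
) -> SpectralMatrix:
    """Segment-wise integer-lag alignment against a reference spectrum.

    Each segment of each spectrum is shifted by the lag (bounded by
    ``max_shift_ppm``) that maximizes its cross-correlation with the
    corresponding reference segment; vacated points are filled by edge
    extension.  The axis is unchanged.  Ties prefer the smaller |lag|.
    """
    step = _check_uniform(X.ppm)
    if max_shift_ppm < 0:
        raise ValueError("max shift must be >= 0")
    seg_pts = int(round(segment_ppm / step))
    if seg_pts < 3:
        raise ValueError("segment length must span at least 3 grid points")
    max_lag = int(np.floor(max_shift_ppm / step + _AXIS_TOL))

    if reference == "median":
        ref = np.median(X.data, axis=0)
    else:
        ref = X.data[int(reference)]

    out = X.data.copy()
    if max_lag > 0:
        lags = np.arange(-max_lag, max_lag + 1)
        # stable preference for small |lag| on ties
        lag_order = lags[np.argsort(np.abs(lags), kind="stable")]
        n_pts = X.ppm.size
        for start in range(0, n_pts, seg_pts):
            stop = min(start + seg_pts, n_pts)
            if stop - start < 3:
                continue
            ref_seg = ref[start:stop]
            m = stop - start
            for i in range(X.n_samples):
                seg = X.data[i, start:stop]
                best_score, best = -np.inf, 0
                for lag in lag_order:
                    # score on the overlap only: edge-padded points would
                    # bias monotone segments toward spurious shifts
                    a, b = max(0, lag), m + min(0, lag)
                    score = float(ref_seg[a:b] @ seg[a - lag:b - lag])
                    if score > best_score + 1e-12:
                        best_score, best = score, lag
                if best:
                    out[i, start:stop] = _shift_segment(seg, best)

    return SpectralMatrix(
        ppm=X.ppm.copy(), data=out, sample_ids=list(X.sample_ids),
        provenance=X.provenance + ("align",), excluded=X.excluded,
    )


# ---------------------------------------------------------------------------
# exclusion and binning
# ---------------------------------------------------------------------------


def exclude_regions(X, regions):
    """Remove points/bins whose centers fall inside any closed interval.

    Works on a SpectralMatrix or a BinnedMatrix; relative order of the
    remaining variables is preserved.  Excluding everything is an error.
    """
    regions = [(float(lo), float(hi)) for lo, hi in regions]
    for lo, hi in regions:
        if hi < lo:
            raise ValueError(f"malformed interval ({lo}, {hi})")

    if isinstance(X, SpectralMatrix):
        centers = X.ppm
    elif isinstance(X, BinnedMatrix):
        centers = X.centers
    else:
        raise TypeError("expected SpectralMatrix or BinnedMatrix")

    keep = np.ones(centers.size, dtype=bool)
    for lo, hi in regions:
        keep &= ~((centers >= lo) & (centers <= hi))
    if not keep.any():
        raise ValueError("exclusion removed every variable")

    new_excl = tuple(X.excluded) + tuple(regions)
    if isinstance(X, SpectralMatrix):
        return SpectralMatrix(
            ppm=X.ppm[keep], data=X.data[:, keep],
            sample_ids=list(X.sample_ids),
            provenance=X.provenance + ("exclude",), excluded=new_excl,
        )
    return replace(
        X, edges=X.edges[keep], centers=X.centers[keep],
        data=X.data[:, keep], excluded=new_excl,
        original_sd=None if X.original_sd is None else X.original_sd[keep],
        col_means=None if X.col_means is None else X.col_means[keep],
        zero_variance=None if X.zero_variance is None else X.zero_variance[keep],
        pqn_reference=None if X.pqn_reference is None else X.pqn_reference[keep],
    )


def bin_spectra(
    X: SpectralMatrix,
    ppm_range: tuple[float, float] = (0.5, 9.8),
    width: float = 0.04,
) -> BinnedMatrix:
    """Sum-bin a spectral matrix into half-open buckets
    [low + i·w, low + (i+1)·w) tiling the range; a trailing partial bin
    is dropped, as are empty bins and bins whose centers fall in a
    previously excluded region.  Summing conserves the total intensity of
    the retained points.
    """
    low, high = map(float, ppm_range)
    if width <= 0:
        raise ValueError("bin width must be > 0")
    if width > high - low:
        raise ValueError("bin width exceeds the requested range")
    if np.any(np.diff(X.ppm) <= 0):
        raise ValueError("ppm axis must be strictly increasing")

    n_bins = int(np.floor((high - low) / width + _AXIS_TOL))
    idx = np.floor((X.ppm - low) / width + _AXIS_TOL).astype(int)
    in_range = (X.ppm >= low) & (idx >= 0) & (idx < n_bins)

    data = np.zeros((X.n_samples, n_bins))
    counts = np.bincount(idx[in_range], minlength=n_bins)
    for i in range(X.n_samples):
        data[i] = np.bincount(idx[in_range], weights=X.data[i, in_range],
                              minlength=n_bins)

    edges = np.column_stack([low + width * np.arange(n_bins),
                             low + width * (np.arange(n_bins) + 1)])
    centers = edges.mean(axis=1)

    keep = counts > 0
    for lo, hi in X.excluded:
        keep &= ~((centers >= lo) & (centers <= hi))
    if not keep.any():
        raise ValueError("no bins retained")

    return BinnedMatrix(
        edges=edges[keep], centers=centers[keep], data=data[:, keep],
        sample_ids=list(X.sample_ids), excluded=tuple(X.excluded),
    )


# ---------------------------------------------------------------------------
# normalization and scaling
# ---------------------------------------------------------------------------


def pqn_normalize(
    B: BinnedMatrix,
    reference: str | np.ndarray | list[str] = "median",
) -> BinnedMatrix:
    """Probabilistic quotient normalization.

    Rows are first divided by their totals (integral normalization); the
    reference is the element-wise median of the integral-normalized
    matrix (default), the median over a named subset of samples, or an
    explicit reference row; each row is then divided by the median of its
    quotients against the reference.  After the call the median quotient
    of every row versus the reference is exactly 1.

    The product total × median-quotient per sample estimates that
    sample's dilution factor and is stored in ``dilution_estimates``.
    """
    if B.scaled:
        raise ValueError("PQN must run before centering/scaling")
    totals = B.data.sum(axis=1)
    bad = np.where(totals <= 0)[0]
    if bad.size:
        raise ValueError(
            f"sample {B.sample_ids[bad[0]]!r} has non-positive total intensity"
        )
    Xn = B.data / totals[:, None]

    if isinstance(reference, str) and reference == "median":
        ref = np.median(Xn, axis=0)
    elif isinstance(reference, (list, tuple)):
        rows = [B.sample_ids.index(s) for s in reference]
        ref = np.median(Xn[rows], axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (B.centers.size,):
            raise ValueError("explicit reference must have one value per bin")

    pos = ref > 0
    if not pos.any():
        raise ValueError("reference spectrum is everywhere non-positive")
    quotients = np.median(Xn[:, pos] / ref[pos], axis=1)
    out = Xn / quotients[:, None]

    return replace(
        B, data=out, normalized=True, pqn_reference=ref,
        dilution_estimates=totals * quotients,
    )


def center_and_pareto_scale(B: BinnedMatrix) -> BinnedMatrix:
    """Mean-center each bin and divide by the square root of its sample
    SD (Pareto scaling).  Zero-variance bins are centered, left unscaled
    and flagged; original SDs and means are stored for back-scaling and
    projection of new samples.
    """
    if B.n_samples < 2:
        raise ValueError("scaling needs at least 2 samples")
    if not B.normalized:
        raise ValueError("center/Pareto scaling must follow normalization")
    if B.scaled:
        raise ValueError("matrix is already scaled")
    means = B.data.mean(axis=0)
    sd = B.data.std(axis=0, ddof=1)
    zero = sd == 0
    denom = np.where(zero, 1.0, np.sqrt(sd))
    out = (B.data - means) / denom
    return replace(B, data=out, scaled=True, original_sd=sd,
                   col_means=means, zero_variance=zero)


def apply_scaling(B_new: BinnedMatrix, trained: BinnedMatrix) -> BinnedMatrix:
    """Project new samples with a previously fitted centering/scaling."""
    if trained.original_sd is None or trained.col_means is None:
        raise ValueError("trained matrix carries no scaling constants")
    if B_new.centers.size != trained.centers.size:
        raise ValueError("bin layout mismatch")
    denom = np.where(trained.zero_variance, 1.0, np.sqrt(trained.original_sd))
    out = (B_new.data - trained.col_means) / denom
    return replace(B_new, data=out, scaled=True,
                   original_sd=trained.original_sd,
                   col_means=trained.col_means,
                   zero_variance=trained.zero_variance)


#: the water/urea exclusion window used throughout urinary work.
WATER_UREA_PPM = (4.2, 5.9)


def standard_preprocess(
    X: SpectralMatrix,
    segment_ppm: float = 0.2,
    max_shift_ppm: float = 0.02,
    exclude: tuple[tuple[float, float], ...] = (WATER_UREA_PPM,),
    bin_range: tuple[float, float] = (0.5, 9.8),
    bin_width: float = 0.04,
    pqn_reference="median",
    align: bool = True,
):
    """Full chain: align → exclude → bin → PQN → center/Pareto.

    Returns ``(normalized, scaled)`` — the PQN-normalized unscaled matrix
    (consumed by univariate integration and STOCSY) and its
    centered/Pareto-scaled counterpart (consumed by OPLS-DA).
    """
    if align and max_shift_ppm > 0:
        X = align_spectra(X, segment_ppm, max_shift_ppm)
    if exclude:
        X = exclude_regions(X, exclude)
    binned = bin_spectra(X, bin_range, bin_width)
    normalized = pqn_normalize(binned, pqn_reference)
    scaled = center_and_pareto_scale(normalized)
    return normalized, scaled
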