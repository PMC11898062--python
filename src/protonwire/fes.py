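"""Free-energy profile reconstruction from umbrella windows (WHAM).

The estimation core follows a model/results layout: :class:`UmbrellaWHAM`
holds the windowed zeta samples and bias definitions; ``fit()`` runs the
self-consistent WHAM iteration and returns a :class:`FreeEnergyResult`
carrying the profile G(zeta), the per-window free-energy shifts f_i,
convergence diagnostics, and methods for bootstrap confidence bands,
feature extraction, classification, plotting and a text summary.

WHAM solves, on a common zeta grid with bins m and windows i,

    p_m = sum_i n_im / sum_i N_i exp(-beta (B_im - f_i))
    f_i = -kT ln sum_m p_m exp(-beta B_im)

iterated until the shifts are stationary, with B_im the umbrella bias of
window i evaluated at bin m.  G = -kT ln p, anchored so the sampled minimum
is zero.  Confidence bands are percentile intervals from a per-window block
bootstrap (block length twice the integrated autocorrelation time of zeta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .units import KB
from .sampling import TrajectorySegment, histogram_overlap

__all__ = [
    "WindowHistogram",
    "FreeEnergyProfile",
    "UmbrellaWHAM",
    "FreeEnergyResult",
    "discard_equilibration",
    "wham_solve",
    "bootstrap_profile",
    "check_overlap",
    "integrated_autocorr_time",
]


@dataclass
class WindowHistogram:
    """Binned zeta samples of one umbrella window plus its WHAM unknown f_i."""

    window_id: int
    zeta0: float
    k: float
    bin_edges: np.ndarray
    counts: np.ndarray
    n_samples: int
    f_i: float = 0.0

    def __post_init__(self):
        if np.any(self.counts < 0):
            raise ValueError("negative histogram counts")
        if int(self.counts.sum()) != self.n_samples:
            raise ValueError("histogram counts do not sum to n_samples")


@dataclass
class FreeEnergyProfile:
    """G(zeta) on a grid of bin midpoints, kJ/mol, min-anchored at zero."""

    zeta: np.ndarray
    G: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    anchor: str = "min"
    metadata: dict = field(default_factory=dict)

    def sampled_mask(self) -> np.ndarray:
        return np.isfinite(self.G)

    def to_frame(self):
        import pandas as pd

        data = {"zeta": self.zeta, "G_kJmol": self.G}
        if self.ci_low is not None:
            data["ci_low"] = self.ci_low
            data["ci_high"] = self.ci_high
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def discard_equilibration(
    segments: list[TrajectorySegment],
    fraction: float = 0.2,
    duration: float | None = None,
) -> list[TrajectorySegment]:
    """Drop the leading equilibration part of every window.

    Either a fraction of the samples (default 0.2, i.e. 0.1 ns of a 0.5 ns
    window) or an explicit duration in ps.  The duration must be shorter
    than every segment.
    """
    out = []
    for seg in segments:
        if duration is not None:
            ncut = int(np.searchsorted(seg.times, duration, side="right"))
            if ncut >= len(seg.times):
                raise ValueError(
                    f"window {seg.window_id}: discard duration {duration} ps "
                    f">= segment length {seg.times[-1]} ps"
                )
        else:
            if not (0.0 <= fraction < 1.0):
                raise ValueError("fraction must be in [0, 1)")
            ncut = int(len(seg.times) * fraction)
        out.append(
            TrajectorySegment(
                window_id=seg.window_id,
                spec=seg.spec,
                times=seg.times[ncut:],
                zeta=None if seg.zeta is None else seg.zeta[ncut:],
                t_kin=seg.t_kin[ncut:],
                energies=None if seg.energies is None else seg.energies[ncut:],
                positions=None if seg.positions is None else seg.positions[ncut:],
                final_positions=seg.final_positions,
            )
        )
    return out


def integrated_autocorr_time(x: np.ndarray) -> float:
    """Integrated autocorrelation time in units of samples (>= 0.5).

    Sokal's self-consistent windowing: tau is summed up to the smallest lag
    W with W >= 5 tau(W), which avoids the downward bias of truncating at
    the first noisy zero crossing.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < 4:
        return 0.5
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var <= 0:
        return 0.5
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(fx * np.conj(fx), nfft)[:n].real
    acf = acf / acf[0]
    tau = 0.5
    for w in range(1, min(n // 2, 20000)):
        tau += acf[w]
        if w >= 5.0 * tau:
            break
    return float(max(tau, 0.5))


def check_overlap(histograms: list[WindowHistogram]):
    """Pairwise shared-area matrix plus pass/fail for adjacent window pairs.

    Returns ``(matrix, report)`` where *report* lists, for each pair of
    windows adjacent in zeta0, the overlap and whether it reaches 0.10.
    """
    if len(histograms) < 2:
        raise ValueError("need at least two windows to check overlap")
    order = np.argsort([h.zeta0 for h in histograms])
    hs = [histograms[i] for i in order]
    n = len(hs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            mat[i, j] = histogram_overlap(hs[i].counts, hs[j].counts)
    report = []
    for a, b in zip(hs[:-1], hs[1:]):
        ov = histogram_overlap(a.counts, b.counts)
        report.append(
            {
                "pair": (a.window_id, b.window_id),
                "centers": (a.zeta0, b.zeta0),
                "overlap": ov,
                "ok": ov >= 0.10,
            }
        )
    return mat, report


def _segments_to_histograms(
    segments: list[TrajectorySegment], bin_edges: np.ndarray
) -> list[WindowHistogram]:
    out = []
    for seg in segments:
        if seg.zeta is None:
            raise ValueError(f"window {seg.window_id} has no zeta series")
        counts, _ = np.histogram(seg.zeta, bins=bin_edges)
        out.append(
            WindowHistogram(
                window_id=seg.window_id,
                zeta0=seg.spec.zeta0,
                k=seg.spec.k,
                bin_edges=bin_edges,
                counts=counts,
                n_samples=int(counts.sum()),
            )
        )
    return out


def _wham_core(counts, bias, n_i, beta, tol, max_iter, mask=None):
    """Self-consistent WHAM iteration on pre-binned data.

    counts: (n_windows, n_bins); bias: (n_windows, n_bins) kJ/mol;
    n_i: samples per window.  Returns (p, f, n_iter, residual).

    When *mask* (n_windows, n_bins, boolean) is given, each window's
    normalization runs over its masked bins only.  This models a window
    that was kinetically confined to one basin of its biased ensemble as
    sampling that basin's conditional distribution (a reflecting wall at
    the edge of its visited range) instead of pretending it equilibrated
    over the whole coordinate.
    """
    n_w, n_b = counts.shape
    tot = counts.sum(axis=0)
    f = np.zeros(n_w)
    expb = np.exp(-beta * (bias - bias.min()))
    if mask is not None:
        expb = expb * mask
    resid = np.inf
    it = 0
    sampled = tot > 0
    for it in range(1, max_iter + 1):
        num = tot
        denom = (n_i[:, None] * expb * np.exp(beta * f)[:, None]).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(sampled & (denom > 0), num / denom, 0.0)
        z = p.sum()
        if z <= 0:
            raise RuntimeError("WHAM produced an empty density")
        p = p / z
        with np.errstate(divide="ignore"):
            fnew = -np.log((p[None, :] * expb).sum(axis=1)) / beta
        fnew = fnew - fnew[0]
        resid = float(np.max(np.abs(fnew - f)))
        f = fnew
        if resid < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations (residual {resid:.2e} kJ/mol)"
        )
    return p, f, it, resid


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class UmbrellaWHAM:
    """WHAM model over umbrella-window zeta samples.

    Parameters
    ----------
    zeta_series : list of 1-D arrays
        Per-window zeta samples (after equilibration discard).
    centers, force_constants : arrays
        Umbrella centers zeta0 and force constants k (kJ/mol per unit
        zeta^2) for each window.
    temperature : float
        Sampling temperature, K.
    bin_width : float
        Width of the zeta bins (profile grid resolution).
    """

    def __init__(
        self,
        zeta_series,
        centers,
        force_constants,
        temperature: float = 310.0,
        bin_width: float = 0.01,
        zeta_range: tuple[float, float] = (0.0, 1.0),
        oversample: int = 10,
    ):
        self.zeta_series = [np.asarray(z, float) for z in zeta_series]
        self.centers = np.asarray(centers, float)
        self.force_constants = np.asarray(force_constants, float)
        if not (len(self.zeta_series) == len(self.centers) == len(self.force_constants)):
            raise ValueError("zeta_series, centers and force_constants disagree in length")
        self.temperature = float(temperature)
        lo, hi = zeta_range
        lo = min(lo, min(z.min() for z in self.zeta_series))
        hi = max(hi, max(z.max() for z in self.zeta_series))
        n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
        self.bin_edges = lo + bin_width * np.arange(n_bins + 1)
        self.bin_mid = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        # WHAM treats the bias as constant within a bin; stiff refinement
        # windows vary strongly across 0.01, so the self-consistent solve
        # runs on an oversampled internal grid and aggregates afterwards.
        self.oversample = max(int(oversample), 1)
        fine_width = bin_width / self.oversample
        n_fine = n_bins * self.oversample
        self._fine_edges = lo + fine_width * np.arange(n_fine + 1)
        self._fine_mid = 0.5 * (self._fine_edges[:-1] + self._fine_edges[1:])

    @classmethod
    def from_segments(
        cls,
        segments: list[TrajectorySegment],
        temperature: float = 310.0,
        bin_width: float = 0.01,
        equilibration: float = 0.2,
    ) -> "UmbrellaWHAM":
        """Build the model from sampled segments, discarding equilibration."""
        if equilibration:
            segments = discard_equilibration(segments, fraction=equilibration)
        return cls(
            [s.zeta for s in segments],
            [s.spec.zeta0 for s in segments],
            [s.spec.k for s in segments],
            temperature=temperature,
            bin_width=bin_width,
        )

    # -- internals ---------------------------------------------------------
    def _histograms(self, zeta_series=None) -> list[WindowHistogram]:
        series = self.zeta_series if zeta_series is None else zeta_series
        out = []
        for i, z in enumerate(series):
            counts, _ = np.histogram(z, bins=self.bin_edges)
            out.append(
                WindowHistogram(i, self.centers[i], self.force_constants[i],
                                self.bin_edges, counts, int(counts.sum()))
            )
        return out

    def _require_chain_overlap(self, counts, centers):
        """All windows must form one connected overlap component.

        Windows are linked when they share a sampled bin; WHAM can only fix
        the relative offsets of window groups that are connected through
        such links.  Raises naming the zeta gap between components.
        """
        n = len(counts)
        # supports dilated by half an output bin: windows that close to each
        # other are pinned to within the output resolution by the bias model
        t = max(self.oversample // 2, 1)
        kern = np.ones(2 * t + 1)
        support = [np.convolve(c > 0, kern, mode="same") > 0 for c in counts]
        # union-find over shared-support links
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if np.any(support[i] & support[j]):
                    parent[find(i)] = find(j)
        roots = {find(i) for i in range(n)}
        if len(roots) > 1:
            comps = {}
            for i in range(n):
                sup = np.nonzero(support[i])[0]
                lo = self._fine_mid[sup[0]] if sup.size else centers[i]
                hi = self._fine_mid[sup[-1]] if sup.size else centers[i]
                comps.setdefault(find(i), []).append((lo, hi))
            groups = sorted(
                (min(a for a, _ in v), max(b for _, b in v)) for v in comps.values()
            )
            gap = ", ".join(
                f"({a[1]:.3f} .. {b[0]:.3f})" for a, b in zip(groups[:-1], groups[1:])
            )
            raise RuntimeError(
                f"umbrella windows fall into {len(roots)} disconnected overlap "
                f"groups; unsampled zeta gap(s): {gap}"
            )

    def _solve(self, zeta_series=None, tol=1e-8, max_iter=100000, check=True):
        series = self.zeta_series if zeta_series is None else zeta_series
        counts = np.array(
            [np.histogram(z, bins=self._fine_edges)[0] for z in series], dtype=float
        )
        if check and len(series) > 1:
            self._require_chain_overlap(counts, self.centers)
        n_i = counts.sum(axis=1)
        beta = 1.0 / (KB * self.temperature)
        dz = self._fine_mid[None, :] - self.centers[:, None]
        bias = 0.5 * self.force_constants[:, None] * dz * dz
        # per-window support hull (visited range + one output bin of pad):
        # a window confined by an internal barrier contributes the
        # conditional density on its reachable range only
        mask = np.zeros(counts.shape, dtype=bool)
        pad = self.oversample
        for i, c in enumerate(counts):
            nz = np.nonzero(c)[0]
            if nz.size:
                mask[i, max(nz[0] - pad, 0): nz[-1] + pad + 1] = True
        p, f, it, resid = _wham_core(counts, bias, n_i, beta, tol, max_iter, mask=mask)
        p_coarse = p.reshape(len(self.bin_mid), self.oversample).sum(axis=1)
        with np.errstate(divide="ignore"):
            G = np.where(
                p_coarse > 0,
                -np.log(np.where(p_coarse > 0, p_coarse, 1.0)) / beta,
                np.nan,
            )
        G = G - np.nanmin(G)
        return G, p_coarse, f, it, resid

    # -- API ---------------------------------------------------------------
    def fit(self, tol: float = 1e-8, max_iter: int = 100000) -> "FreeEnergyResult":
        """Run the WHAM self-consistent iteration to |df| < tol (kJ/mol)."""
        G, p, f, it, resid = self._solve(tol=tol, max_iter=max_iter)
        hists = self._histograms()
        for h, fi in zip(hists, f):
            h.f_i = float(fi)
        profile = FreeEnergyProfile(
            zeta=self.bin_mid.copy(),
            G=G,
            metadata={
                "temperature_K": self.temperature,
                "n_windows": len(self.zeta_series),
                "n_samples": int(sum(len(z) for z in self.zeta_series)),
            },
        )
        return FreeEnergyResult(self, profile, f, it, resid, hists)


class FreeEnergyResult:
    """Fitted free-energy profile with diagnostics and follow-up analyses."""

    def __init__(self, model, profile, window_shifts, n_iter, residual, histograms):
        self.model = model
        self.profile = profile
        self.window_shifts = np.asarray(window_shifts)
        self.n_iter = int(n_iter)
        self.residual = float(residual)
        self.histograms = histograms
        self._features = None
        self._classification = None

    # -- uncertainties -----------------------------------------------------
    def bootstrap(self, n_cycles: int = 30, seed: int = 0) -> "FreeEnergyResult":
        """95% confidence bands from a per-window block bootstrap.

        Blocks are time-contiguous with length twice the integrated
        autocorrelation time of zeta in that window (floor 10 samples);
        windows too short to hold two blocks are resampled whole, with a
        warning.  The default of 30 resampling cycles matches the umbrella
        protocol the package targets.
        """
        rng = np.random.default_rng(seed)
        series = self.model.zeta_series
        blocks_per_window = []
        for z in series:
            blk = max(int(round(2.0 * integrated_autocorr_time(z))), 10)
            if len(z) < 2 * blk:
                warnings.warn(
                    "window too short for block bootstrap; resampling whole window "
                    "(bands may be too narrow)"
                )
                blk = len(z)
            blocks_per_window.append(blk)

        boots = []
        for _ in range(n_cycles):
            resampled = []
            for z, blk in zip(series, blocks_per_window):
                n = len(z)
                if blk >= n:
                    resampled.append(z[rng.integers(0, n, size=n)] if n else z)
                    continue
                starts = rng.integers(0, n - blk + 1, size=int(np.ceil(n / blk)))
                chunks = [z[s : s + blk] for s in starts]
                resampled.append(np.concatenate(chunks)[:n])
            try:
                # resamples tolerate a looser WHAM tolerance: 1e-6 kJ/mol is
                # far below any band width of interest
                G, *_ = self.model._solve(
                    zeta_series=resampled, check=False, tol=1e-6, max_iter=50000
                )
            except RuntimeError:
                continue
            boots.append(G)
        if not boots:
            raise RuntimeError("every bootstrap resample failed to converge")
        stack = np.array(boots)
        # normal-approximation interval centered on the full-data estimate:
        # more stable than raw percentiles at ~30 resampling cycles
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sd = np.nanstd(stack, axis=0, ddof=1)
        self.profile.ci_low = self.profile.G - 1.96 * sd
        self.profile.ci_high = self.profile.G + 1.96 * sd
        self.profile.metadata["bootstrap_cycles"] = len(boots)
        return self

    # -- analyses ----------------------------------------------------------
    def features(self, **kwargs):
        from .profiles import extract_features

        self._features = extract_features(self.profile, **kwargs)
        return self._features

    def classify(self, thresholds=None):
        from .profiles import classify_profile

        feats = self._features if self._features is not None else self.features()
        self._classification = classify_profile(feats, thresholds)
        return self._classification

    def overlap_report(self):
        return check_overlap(self.histograms)

    def plot(self, ax=None):
        """Plot G(zeta) with confidence bands, if computed."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        p = self.profile
        ax.plot(p.zeta, p.G, lw=1.5, color="tab:blue")
        if p.ci_low is not None:
            ax.fill_between(p.zeta, p.ci_low, p.ci_high, alpha=0.3, color="tab:blue")
        ax.set_xlabel(r"proton coordinate $\zeta$")
        ax.set_ylabel(r"$\Delta G$ (kJ/mol)")
        return ax

    def summary(self) -> str:
        p = self.profile
        mask = p.sampled_mask()
        lines = [
            "Umbrella WHAM free-energy profile",
            "=" * 48,
            f"windows:            {len(self.model.zeta_series)}",
            f"samples:            {p.metadata.get('n_samples')}",
            f"temperature:        {self.model.temperature:.1f} K",
            f"bins (sampled):     {mask.size} ({int(mask.sum())})",
            f"WHAM iterations:    {self.n_iter}  (residual {self.residual:.2e} kJ/mol)",
            f"max G (sampled):    {np.nanmax(p.G):.2f} kJ/mol",
        ]
        if p.ci_low is not None:
            width = np.nanmedian(p.ci_high[mask] - p.ci_low[mask])
            lines.append(
                f"bootstrap cycles:   {p.metadata.get('bootstrap_cycles')}  "
                f"(median 95% band {width:.2f} kJ/mol)"
            )
        if self._features is not None:
            f = self._features
            lines += [
                "-" * 48,
                f"forward barrier:    {f.forward_barrier:.2f} kJ/mol",
                f"reverse barrier:    {f.reverse_barrier:.2f} kJ/mol",
                f"reaction dG_R:      {f.delta_G_R:+.2f} kJ/mol",
            ]
        if self._classification is not None:
            lines.append(f"classification:     {self._classification.category}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def wham_solve(
    histograms_or_segments,
    temperature: float = 310.0,
    tol: float = 1e-8,
    max_iter: int = 100000,
    bin_width: float = 0.01,
) -> FreeEnergyProfile:
    """WHAM on segments (preferred) or pre-binned histograms."""
    if histograms_or_segments and isinstance(histograms_or_segments[0], TrajectorySegment):
        model = UmbrellaWHAM.from_segments(
            histograms_or_segments, temperature=temperature,
            bin_width=bin_width, equilibration=0.0,
        )
        return model.fit(tol=tol, max_iter=max_iter).profile
    hists: list[WindowHistogram] = histograms_or_segments
    edges = hists[0].bin_edges
    mid = 0.5 * (edges[:-1] + edges[1:])
    counts = np.array([h.counts for h in hists], dtype=float)
    centers = np.array([h.zeta0 for h in hists])
    ks = np.array([h.k for h in hists])
    if len(hists) > 1:
        order = np.argsort(centers)
        for ia, ib in zip(order[:-1], order[1:]):
            if not np.any((counts[ia] > 0) & (counts[ib] > 0)):
                raise RuntimeError(
                    "non-overlapping umbrella windows: no shared sampled bin "
                    f"between centers {centers[ia]:.3f} and {centers[ib]:.3f}"
                )
    beta = 1.0 / (KB * temperature)
    dz = mid[None, :] - centers[:, None]
    bias = 0.5 * ks[:, None] * dz * dz
    p, f, _, _ = _wham_core(counts, bias, counts.sum(axis=1), beta, tol, max_iter)
    with np.errstate(divide="ignore"):
        G = np.where(p > 0, -np.log(np.where(p > 0, p, 1.0)) / beta, np.nan)
    G = G - np.nanmin(G)
    for h, fi in zip(hists, f):
        h.f_i = float(fi)
    return FreeEnergyProfile(zeta=mid, G=G, metadata={"temperature_K": temperature})


def bootstrap_profile(
    segments: list[TrajectorySegment],
    n_cycles: int = 30,
    temperature: float = 310.0,
    bin_width: float = 0.01,
    seed: int = 0,
    equilibration: float = 0.0,
) -> FreeEnergyProfile:
    """WHAM + block-bootstrap confidence bands, as a single call."""
    model = UmbrellaWHAM.from_segments(
        segments, temperature=temperature, bin_width=bin_width, equilibration=equilibration
    )
    res = model.fit().bootstrap(n_cycles=n_cycles, seed=seed)
    return res.profile
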