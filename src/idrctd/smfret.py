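"""Single-molecule FRET trace analysis and population-histogram modelling.

The pipeline mirrors standard surface-tethered smFRET practice with
camera-based detection and alternating laser excitation (ALEX):

1. :func:`select_single_pairs` keeps molecules with one active donor and
   one active acceptor (direct-excitation signal present, single-step
   photobleaching, donor rise at acceptor bleach).
2. :func:`detect_photobleach` truncates each trace at the first bleach
   step of the summed intensity.
3. :func:`proximity_ratio` computes the raw, uncorrected per-frame FRET
   efficiency E = I_A / (I_A + I_D); no gamma, crosstalk or background
   corrections are applied anywhere.
4. :func:`accumulate_histogram` pools per-frame E values of accepted
   molecules into a population histogram on [0, 1].
5. :class:`FretPopulationModel` fits the binned histogram with a mixture
   of [0, 1]-truncated Gaussian components by maximum likelihood; the
   number of states is chosen by BIC (smallest k within 2 units of the
   minimum). Its results object reports occupancies, peak means, widths as
   full width at half maximum, and SAW-model dye separations.
6. :func:`classify_dynamics` labels molecules static or dynamic from
   anticorrelated donor/acceptor intensity steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .polymer import SawModel, saw_mean_distance

__all__ = [
    "FretTrace",
    "FretHistogram",
    "MixtureComponent",
    "MixtureModel",
    "FretPopulationModel",
    "FretPopulationResults",
    "read_traces_csv",
    "write_traces_csv",
    "select_single_pairs",
    "detect_photobleach",
    "proximity_ratio",
    "accumulate_histogram",
    "last_frame_both_dyes_alive",
    "fit_mixture",
    "classify_dynamics",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


# ---------------------------------------------------------------------------
# trace container and I/O
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class FretTrace:
    """Donor/acceptor/direct-excitation intensities for one molecule."""

    donor: np.ndarray
    acceptor: np.ndarray
    direct_acceptor: np.ndarray
    frame_rate: float = 10.0
    molecule_id: str = "0"

    def __post_init__(self):
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        self.direct_acceptor = np.asarray(self.direct_acceptor, dtype=float)
        n = self.donor.size
        if self.acceptor.size != n or self.direct_acceptor.size != n:
            raise ValueError("channel lengths differ")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        for name in ("donor", "acceptor", "direct_acceptor"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite intensities in {name}")

    @property
    def n_frames(self) -> int:
        return self.donor.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor


def write_traces_csv(traces, path) -> None:
    """Tidy CSV with columns molecule_id, frame, I_D, I_A, I_A_direct."""
    import pandas as pd

    frames = []
    for t in traces:
        frames.append(
            pd.DataFrame(
                {
                    "molecule_id": t.molecule_id,
                    "frame": np.arange(t.n_frames),
                    "I_D": t.donor,
                    "I_A": t.acceptor,
                    "I_A_direct": t.direct_acceptor,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path, frame_rate: float = 10.0) -> list[FretTrace]:
    import pandas as pd

    df = pd.read_csv(path)
    traces = []
    for mol, grp in df.groupby("molecule_id", sort=False):
        grp = grp.sort_values("frame")
        traces.append(
            FretTrace(
                donor=grp["I_D"].to_numpy(),
                acceptor=grp["I_A"].to_numpy(),
                direct_acceptor=grp["I_A_direct"].to_numpy(),
                frame_rate=frame_rate,
                molecule_id=str(mol),
            )
        )
    return traces


# ---------------------------------------------------------------------------
# step / change-point detection
# ---------------------------------------------------------------------------

def robust_noise_sd(x: np.ndarray) -> float:
    """Noise SD from the median absolute deviation of first differences."""
    d = np.diff(np.asarray(x, dtype=float))
    if d.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def _best_split(x: np.ndarray) -> tuple[int, float]:
    """CUSUM-style split: index k maximising |mean(x[:k]) - mean(x[k:])|.

    Returns (k, step size); k is the first index of the right segment.
    """
    n = x.size
    if n < 2:
        return 0, 0.0
    csum = np.cumsum(x)
    k = np.arange(1, n)
    left = csum[:-1] / k
    right = (csum[-1] - csum[:-1]) / (n - k)
    diff = right - left
    # weight by sqrt of harmonic sample size to avoid end-spikes
    w = np.sqrt(k * (n - k) / n)
    i = int(np.argmax(np.abs(diff) * w))
    return int(k[i]), float(diff[i])


def change_points(
    x: np.ndarray, threshold_sd: float = 3.0, min_segment: int = 3
) -> list[int]:
    """Step positions in ``x`` by binary segmentation.

    A split is accepted when the step size exceeds ``threshold_sd`` times
    the robust noise SD of the whole trace (exact steps in noiseless data
    are always accepted). Returned indices mark the first frame after each
    step.
    """
    x = np.asarray(x, dtype=float)
    sd = robust_noise_sd(x)
    floor = max(threshold_sd * sd, 1e-9 * (np.abs(x).max() + 1.0))
    found: list[int] = []

    def recurse(lo: int, hi: int):
        seg = x[lo:hi]
        if seg.size < 2 * min_segment:
            return
        k, step = _best_split(seg)
        if k < min_segment or seg.size - k < min_segment:
            # try interior best split respecting margins
            best = (None, 0.0)
            csum = np.cumsum(seg)
            for kk in range(min_segment, seg.size - min_segment + 1):
                left = csum[kk - 1] / kk
                right = (csum[-1] - csum[kk - 1]) / (seg.size - kk)
                if abs(right - left) > abs(best[1]):
                    best = (kk, right - left)
            if best[0] is None:
                return
            k, step = best
        if abs(step) <= floor:
            return
        found.append(lo + k)
        recurse(lo, lo + k)
        recurse(lo + k, hi)

    recurse(0, x.size)
    return sorted(found)


def detect_photobleach(trace: FretTrace, threshold_sd: float = 3.0) -> int:
    """Index of the last frame before the first bleach step.

    Change-point detection runs on the summed donor + acceptor intensity;
    the first downward step is taken as photobleaching. Returns the last
    frame index when no step is found.
    """
    total = trace.total
    for cp in change_points(total, threshold_sd=threshold_sd):
        before = float(np.mean(total[max(0, cp - 10):cp]))
        after = float(np.mean(total[cp:cp + 10]))
        if after < before:
            return cp - 1
    return trace.n_frames - 1


def last_frame_both_dyes_alive(trace: FretTrace, threshold_sd: float = 3.0) -> int:
    """Last frame before *either* dye photobleaches.

    Donor death shows as a downward step in the summed intensity
    (:func:`detect_photobleach`); acceptor death leaves the sum conserved
    (the donor rises) but shows as a downward step in the direct-excitation
    channel. FRET frames are only meaningful while both dyes live.
    """
    upto = detect_photobleach(trace, threshold_sd=threshold_sd)
    direct = trace.direct_acceptor
    for cp in change_points(direct, threshold_sd=threshold_sd):
        if np.mean(direct[cp:]) < np.mean(direct[:cp]):
            upto = min(upto, cp - 1)
            break
    return upto


# ---------------------------------------------------------------------------
# proximity ratio and histogram
# ---------------------------------------------------------------------------

def proximity_ratio(trace: FretTrace, upto: int | None = None) -> np.ndarray:
    """Raw per-frame E = I_A / (I_A + I_D) up to frame ``upto`` inclusive.

    Frames with zero (or negative) total intensity are flagged NaN and are
    skipped downstream; no corrections are applied.
    """
    if upto is None:
        upto = trace.n_frames - 1
    if not 0 <= upto < trace.n_frames:
        raise IndexError(f"upto={upto} outside trace of {trace.n_frames} frames")
    d = trace.donor[: upto + 1]
    a = trace.acceptor[: upto + 1]
    tot = d + a
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(tot > 0, a / np.where(tot > 0, tot, 1.0), np.nan)
    return e


@dataclass(frozen=True)
class FretHistogram:
    """Pooled per-frame proximity-ratio counts on [0, 1]."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_molecules: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_frames(self) -> int:
        return int(self.counts.sum())

    @property
    def density(self) -> np.ndarray:
        width = np.diff(self.bin_edges)
        total = self.counts.sum()
        return self.counts / (total * width) if total else self.counts * 0.0


def accumulate_histogram(
    traces, bins: int = 50, truncate_at_bleach: bool = True
) -> FretHistogram:
    """Pool per-frame E values of the accepted molecules into fixed bins.

    Each trace contributes every valid frame captured before photobleaching
    of either dye (or all frames when ``truncate_at_bleach`` is false):
    after the acceptor dies the proximity ratio collapses to zero without
    reporting on conformation, so those frames are excluded.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no accepted traces to accumulate")
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts = np.zeros(bins, dtype=int)
    n_valid = 0
    for t in traces:
        upto = last_frame_both_dyes_alive(t) if truncate_at_bleach else t.n_frames - 1
        if upto < 0:
            continue
        e = proximity_ratio(t, upto)
        e = e[np.isfinite(e)]
        e = e[(e >= 0.0) & (e <= 1.0)]
        if e.size:
            c, _ = np.histogram(e, bins=edges)
            counts += c
            n_valid += 1
    if counts.sum() == 0:
        raise ValueError("no valid frames in any trace")
    return FretHistogram(bin_edges=edges, counts=counts, n_molecules=len(traces))


def histogram_from_values(values: np.ndarray, bins: int = 50, n_molecules: int = 0) -> FretHistogram:
    """Histogram directly from an array of proximity ratios (synthetic use)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values) & (values >= 0) & (values <= 1)]
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return FretHistogram(bin_edges=edges, counts=counts, n_molecules=n_molecules)


# ---------------------------------------------------------------------------
# single-pair selection
# ---------------------------------------------------------------------------

def select_single_pairs(
    traces,
    direct_threshold: float = 50.0,
    threshold_sd: float = 3.0,
) -> list[FretTrace]:
    """Accept traces consistent with one active donor and one acceptor.

    Criteria (all required):

    a. mean direct-excitation acceptor signal before its bleach exceeds
       ``direct_threshold`` counts (an acceptor is present),
    b. the summed donor+acceptor intensity and the direct-excitation
       channel each show at most one downward step (single-step
       bleaching; multi-step implies an aggregate),
    c. when the acceptor bleaches before the donor, the donor intensity
       rises at that step (anticorrelation expected of a true pair).
    """
    traces = list(traces)
    if not traces:
        warnings.warn("select_single_pairs called with no traces")
        return []
    accepted = []
    for t in traces:
        direct_cps = [
            cp
            for cp in change_points(t.direct_acceptor, threshold_sd=threshold_sd)
            if np.mean(t.direct_acceptor[cp:]) < np.mean(t.direct_acceptor[:cp])
        ]
        alive_end = direct_cps[0] if direct_cps else t.n_frames
        if alive_end < 2 or np.mean(t.direct_acceptor[:alive_end]) < direct_threshold:
            continue
        total_down = [
            cp
            for cp in change_points(t.total, threshold_sd=threshold_sd)
            if np.mean(t.total[cp:]) < np.mean(t.total[:cp])
        ]
        if len(total_down) > 1 or len(direct_cps) > 1:
            continue
        if direct_cps:
            cp = direct_cps[0]
            donor_bleach = total_down[0] if total_down else t.n_frames
            if cp < donor_bleach - 2 and cp + 2 < t.n_frames:
                pre = np.mean(t.donor[max(0, cp - 10):cp])
                post_end = min(donor_bleach - 1, cp + 10)
                post = np.mean(t.donor[cp:post_end]) if post_end > cp else pre
                if post <= pre:
                    continue
        accepted.append(t)
    return accepted


# ---------------------------------------------------------------------------
# static vs dynamic classification
# ---------------------------------------------------------------------------

def classify_dynamics(
    trace: FretTrace,
    upto: int | None = None,
    threshold_sd: float = 3.0,
    total_tolerance: float = 0.5,
) -> str:
    """Label a molecule ``"static"`` or ``"dynamic"`` (or ``"indeterminate"``).

    Dynamic requires at least one change point in the proximity ratio whose
    donor and acceptor intensity steps are anticorrelated (opposite signs)
    while the summed intensity is conserved: |dD + dA| must not exceed
    ``total_tolerance`` times the larger channel step (plus the noise
    floor). Correlated steps in both channels (focus or stage drift) do
    not count.
    """
    if upto is None:
        upto = detect_photobleach(trace, threshold_sd=threshold_sd)
    if upto + 1 < 20:
        return "indeterminate"
    e = proximity_ratio(trace, upto)
    d = trace.donor[: upto + 1]
    a = trace.acceptor[: upto + 1]
    noise = np.hypot(robust_noise_sd(d), robust_noise_sd(a))
    e_clean = np.nan_to_num(e, nan=float(np.nanmean(e)) if np.isfinite(e).any() else 0.0)
    for cp in change_points(e_clean, threshold_sd=threshold_sd):
        lo, hi = max(0, cp - 10), min(upto + 1, cp + 10)
        dd = float(np.mean(d[cp:hi]) - np.mean(d[lo:cp]))
        da = float(np.mean(a[cp:hi]) - np.mean(a[lo:cp]))
        if dd * da >= 0:
            continue
        if abs(dd + da) <= total_tolerance * max(abs(dd), abs(da)) + 3.0 * noise:
            return "dynamic"
    return "static"


# ---------------------------------------------------------------------------
# truncated-Gaussian mixture fit to the binned histogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureComponent:
    """One Gaussian FRET state: occupancy, peak position, FWHM width."""

    weight: float
    mean: float
    fwhm: float

    @property
    def sigma(self) -> float:
        return self.fwhm / FWHM_PER_SIGMA


@dataclass(frozen=True)
class MixtureModel:
    """Fitted multistate Gaussian description of a FRET population."""

    components: tuple[MixtureComponent, ...]
    log_likelihood: float
    bic: float
    n_frames: int

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def fwhms(self) -> np.ndarray:
        return np.array([c.fwhm for c in self.components])


def _bin_log_probs(edges, means, sigmas):
    """Per-component probability mass in each bin, truncated to [lo, hi]."""
    lo, hi = edges[0], edges[-1]
    cdf_hi = norm.cdf((hi - means) / sigmas)
    cdf_lo = norm.cdf((lo - means) / sigmas)
    denom = np.clip(cdf_hi - cdf_lo, 1e-300, None)
    cdfs = norm.cdf((edges[None, :] - means[:, None]) / sigmas[:, None])
    mass = np.diff(cdfs, axis=1) / denom[:, None]
    return np.clip(mass, 1e-300, None)  # (k, n_bins)


def _neg_log_likelihood(theta, k, edges, counts):
    logits = np.concatenate([theta[: k - 1], [0.0]])
    w = np.exp(logits - logits.max())
    w = w / w.sum()
    means = theta[k - 1 : 2 * k - 1]
    sigmas = np.exp(theta[2 * k - 1 :])
    mass = _bin_log_probs(edges, means, sigmas)
    mix = w @ mass
    return -float(np.sum(counts * np.log(np.clip(mix, 1e-300, None))))


def _fit_k(hist: FretHistogram, k: int, rng: np.random.Generator, n_starts: int,
           warm: MixtureModel | None = None):
    edges, counts = hist.bin_edges, hist.counts
    n = counts.sum()
    centers = hist.centers
    # moment-based starting means: quantiles of the empirical distribution
    cum = np.cumsum(counts) / n
    q = (np.arange(k) + 0.5) / k
    mean0 = np.interp(q, cum, centers)
    starts = [(mean0, np.full(k, 0.08), np.ones(k))]
    if warm is not None and warm.n_components == k - 1:
        # hierarchical start: split the widest component of the (k-1) fit
        i = int(np.argmax(warm.fwhms))
        sig = warm.fwhms / FWHM_PER_SIGMA
        means = np.concatenate(
            [np.delete(warm.means, i),
             [warm.means[i] - 0.5 * sig[i], warm.means[i] + 0.5 * sig[i]]]
        )
        sigmas = np.concatenate([np.delete(sig, i), [0.6 * sig[i], 0.6 * sig[i]]])
        weights = np.concatenate(
            [np.delete(warm.weights, i), [0.5 * warm.weights[i]] * 2]
        )
        order = np.argsort(means)
        starts.append((np.clip(means[order], 0.0, 1.0),
                       np.clip(sigmas[order], 0.01, 0.5), weights[order]))
    while len(starts) < n_starts:
        starts.append((np.sort(rng.uniform(0.02, 0.98, size=k)),
                       rng.uniform(0.03, 0.25, size=k), np.ones(k)))
    best = None
    bounds = (
        [(-10.0, 10.0)] * (k - 1)
        + [(0.0, 1.0)] * k
        + [(np.log(0.008), np.log(0.6))] * k
    )
    for means, sigmas, weights in starts:
        w = np.asarray(weights, float) / np.sum(weights)
        logits = np.log(np.clip(w[:-1], 1e-6, None)) - np.log(np.clip(w[-1], 1e-6, None))
        theta0 = np.concatenate([np.clip(logits, -10, 10), means, np.log(sigmas)])
        res = optimize.minimize(
            _neg_log_likelihood,
            theta0,
            args=(k, edges, counts),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    logits = np.concatenate([theta[: k - 1], [0.0]])
    w = np.exp(logits - logits.max())
    w = w / w.sum()
    means = theta[k - 1 : 2 * k - 1]
    sigmas = np.exp(theta[2 * k - 1 :])
    order = np.argsort(means)
    comps = tuple(
        MixtureComponent(weight=float(w[i]), mean=float(means[i]), fwhm=float(FWHM_PER_SIGMA * sigmas[i]))
        for i in order
    )
    ll = -best.fun
    n_params = 3 * k - 1
    bic = -2.0 * ll + n_params * np.log(n)
    return MixtureModel(components=comps, log_likelihood=ll, bic=bic, n_frames=int(n)), bool(best.success)


class FretPopulationModel:
    """Multistate Gaussian model of a FRET population histogram.

    Fits mixtures of [0, 1]-truncated Gaussians with k = 1..max_components
    components to the binned counts by maximum likelihood, and selects the
    smallest k whose BIC lies within ``bic_margin`` of the minimum (a
    parsimony rule standing in for "minimise the fitting statistics").
    """

    def __init__(self, hist: FretHistogram, max_components: int = 4, bic_margin: float = 2.0):
        if int(np.count_nonzero(hist.counts)) < 3:
            raise ValueError("histogram must have at least 3 occupied bins")
        self.hist = hist
        self.max_components = max_components
        self.bic_margin = bic_margin

    def fit(self, n_starts: int = 8, seed: int = 0) -> "FretPopulationResults":
        rng = np.random.default_rng(seed)
        fits: dict[int, MixtureModel] = {}
        any_converged = False
        prev: MixtureModel | None = None
        for k in range(1, self.max_components + 1):
            model, ok = _fit_k(self.hist, k, rng, n_starts, warm=prev)
            fits[k] = model
            any_converged = any_converged or ok
            prev = model
        if not any_converged:
            raise RuntimeError(
                "mixture fit failed to converge for every component count; "
                f"bics={[round(m.bic, 1) for m in fits.values()]}"
            )
        best_bic = min(m.bic for m in fits.values())
        k_sel = min(k for k, m in fits.items() if m.bic <= best_bic + self.bic_margin)
        return FretPopulationResults(model=self, fits=fits, selected_k=k_sel)


@dataclass
class FretPopulationResults:
    """Fit results: per-k models, the selected model, and summaries."""

    model: FretPopulationModel
    fits: dict[int, MixtureModel]
    selected_k: int

    @property
    def mixture(self) -> MixtureModel:
        return self.fits[self.selected_k]

    @property
    def bic_by_k(self) -> dict[int, float]:
        return {k: m.bic for k, m in self.fits.items()}

    def dye_distances(self, saw: SawModel = SawModel(), statistic: str = "rms") -> np.ndarray:
        """SAW-model <R_DA> (nm) for each fitted state mean."""
        return np.array(
            [saw_mean_distance(c.mean, saw, statistic=statistic) for c in self.mixture.components]
        )

    def summary(self, saw: SawModel | None = SawModel()) -> str:
        m = self.mixture
        lines = [
            "FRET population mixture fit",
            f"  frames: {m.n_frames}   molecules: {self.model.hist.n_molecules}",
            f"  selected states: {self.selected_k} "
            f"(BIC by k: {', '.join(f'{k}:{b:.1f}' for k, b in sorted(self.bic_by_k.items()))})",
            "",
            "  state   occupancy   mean E    width (FWHM)" + ("   <R_DA> (nm)" if saw else ""),
        ]
        dists = self.dye_distances(saw) if saw else [None] * m.n_components
        for i, (c, r) in enumerate(zip(m.components, dists), start=1):
            row = f"  {i:>5d}   {c.weight:9.3f}   {c.mean:6.3f}    {c.fwhm:12.3f}"
            if r is not None:
                row += f"   {r:11.2f}"
            lines.append(row)
        return "\n".join(lines)


def fit_mixture(
    hist: FretHistogram, max_components: int = 4, n_starts: int = 8, seed: int = 0
) -> MixtureModel:
    """Convenience wrapper: fit and return the selected :class:`MixtureModel`."""
    return FretPopulationModel(hist, max_components=max_components).fit(
        n_starts=n_starts, seed=seed
    ).mixture
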