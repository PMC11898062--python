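"""Profile features, bioenergetic feasibility classification, and hop analysis.

A proton-transfer free-energy profile G(zeta) is reduced to a feature
vector (forward/reverse barrier, reaction free energy dG_R, internal
minima/maxima) and classified against bioenergetic thresholds:

* transfers requiring an ascent above ~70 kJ/mol (roughly the full free
  energy released by complete quinol oxidation in the bc1 complex) are
  energetically unfeasible;
* a reverse barrier under 15 kJ/mol signals an unstable product;
* a deep internal minimum traps the excess proton mid-wire (hydronium or
  protonated side chain) and stalls completion;
* steeply downhill profiles (dG_R below -70 kJ/mol) dissipate the available
  free energy on a "hot proton" and cannot be part of a reversible cycle;
* plausible physiological steps combine low-to-medium barriers (up to
  ~45 kJ/mol) with near-thermoneutral reaction free energies
  (|dG_R| < 20 kJ/mol).

Trajectory-level analysis locates the excess proton by proton-count
bookkeeping per protonable site and extracts the debounced Grotthuss hop
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .fes import FreeEnergyProfile
from .topology import SystemTopology

__all__ = [
    "ProfileFeatures",
    "ClassificationThresholds",
    "ProfileClass",
    "extract_features",
    "classify_profile",
    "locate_excess_proton",
    "hop_sequence",
    "HopEvent",
]


@dataclass
class ProfileFeatures:
    """Scalar features of a G(zeta) profile, kJ/mol."""

    forward_barrier: float
    reverse_barrier: float
    delta_G_R: float
    minima: list = field(default_factory=list)  # (zeta, G, trap_depth)
    maxima: list = field(default_factory=list)  # (zeta, G)
    monotone: str | None = None  # "up" | "down" | None


@dataclass(frozen=True)
class ClassificationThresholds:
    """Decision thresholds, kJ/mol.  Defaults follow the bioenergetic
    budget of the Q-cycle (~70 kJ/mol for complete quinol oxidation)."""

    uphill: float = 70.0          # required ascent / dG_R above -> unfeasible
    unstable_reverse: float = 15.0  # reverse barrier below -> unstable product
    trap_depth: float = 20.0      # internal minimum this far below both
    #                              flanking maxima -> trapped intermediate
    trap_escape: float = 70.0     # escape barrier above -> trapped regardless
    downhill: float = -70.0       # dG_R below -> dissipative
    plausible_barrier: float = 45.0
    plausible_dgr: float = 20.0


@dataclass
class ProfileClass:
    category: str  # infeasible_uphill | unstable_product | trapped_intermediate
    #               | dissipative_downhill | plausible
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    reason: str = ""


def _smooth(G: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    window = min(window if window % 2 == 1 else window + 1, len(G) - (1 - len(G) % 2))
    if window <= polyorder + 1:
        return G
    return savgol_filter(G, window, polyorder)


def extract_features(
    profile: FreeEnergyProfile,
    smooth_window: int = 11,
    polyorder: int = 3,
    min_prominence: float = 1.0,
) -> ProfileFeatures:
    """Stationary points and barriers from a (smoothed) profile.

    The profile is restricted to its sampled bins, smoothed with a local
    polynomial (Savitzky-Golay) fit, and scanned for interior minima and
    maxima with prominence above *min_prominence* kJ/mol.  The reactant
    basin is the minimum closest to zeta = 0 (or the zeta = 0 endpoint for a
    monotone profile), the product basin the one closest to zeta = 1;
    dG_R = G(product) - G(reactant) and the forward barrier is the highest
    point on the path between the two basins, relative to the reactant.
    """
    mask = profile.sampled_mask()
    z = profile.zeta[mask]
    G = profile.G[mask]
    if len(z) < 20:
        raise ValueError("profile has fewer than 20 sampled bins")
    Gs = _smooth(G, smooth_window, polyorder)

    from scipy.signal import find_peaks

    imax, _ = find_peaks(Gs, prominence=min_prominence)
    imin, _ = find_peaks(-Gs, prominence=min_prominence)

    monotone = None
    if len(imax) == 0 and len(imin) == 0:
        span = Gs[-1] - Gs[0]
        monotone = "up" if span >= 0 else "down"

    # basin indices: interior minima plus the endpoints
    basin_idx = sorted({0, len(Gs) - 1, *imin.tolist()})
    react = min((i for i in basin_idx), key=lambda i: (z[i]))
    prod = max((i for i in basin_idx), key=lambda i: (z[i]))
    # snap endpoints to the nearest interior minimum if it is essentially
    # the same basin edge (endpoint higher than adjacent minimum by < kT-ish
    # is still the same basin; keep endpoints as basins by default)
    lo, hi = min(react, prod), max(react, prod)
    seg = Gs[lo : hi + 1]
    top = float(np.max(seg))
    g_react = float(Gs[react])
    g_prod = float(Gs[prod])
    forward = top - g_react
    reverse = top - g_prod
    dgr = g_prod - g_react

    minima = []
    for i in imin:
        left = Gs[: i + 1]
        right = Gs[i:]
        depth = min(float(np.max(left) - Gs[i]), float(np.max(right) - Gs[i]))
        minima.append((float(z[i]), float(Gs[i]), depth))
    maxima = [(float(z[i]), float(Gs[i])) for i in imax]

    return ProfileFeatures(
        forward_barrier=forward,
        reverse_barrier=reverse,
        delta_G_R=dgr,
        minima=minima,
        maxima=maxima,
        monotone=monotone,
    )


def classify_profile(
    features: ProfileFeatures,
    thresholds: ClassificationThresholds | None = None,
) -> ProfileClass:
    """Total, deterministic feasibility classification of a profile.

    Rules are applied in a fixed order (uphill -> trapped -> dissipative ->
    unstable product -> plausible).  Threshold sides: ascents strictly above
    the uphill threshold are unfeasible; reverse barriers strictly below the
    unstable threshold flag an unstable product; a profile is plausible when
    the forward barrier is <= 45 kJ/mol and |dG_R| < 20 kJ/mol.  Profiles
    matching no rule are resolved to the nearest violated side (uphill- or
    downhill-leaning), keeping the classification total.
    """
    t = thresholds or ClassificationThresholds()
    f = features
    vals = [f.forward_barrier, f.reverse_barrier, f.delta_G_R]
    if not np.all(np.isfinite(vals)):
        raise ValueError("profile features are not finite")

    if f.delta_G_R > t.uphill or f.forward_barrier > t.uphill:
        return ProfileClass(
            "infeasible_uphill", t,
            f"required ascent {max(f.delta_G_R, f.forward_barrier):.1f} kJ/mol "
            f"exceeds {t.uphill:.0f}",
        )
    deep = [m for m in f.minima if m[2] >= t.trap_depth]
    if deep:
        z_t, _, depth = max(deep, key=lambda m: m[2])
        return ProfileClass(
            "trapped_intermediate", t,
            f"internal minimum at zeta={z_t:.2f} lies {depth:.1f} kJ/mol below "
            f"both flanking maxima (threshold {t.trap_depth:.0f})",
        )
    if f.delta_G_R < t.downhill:
        return ProfileClass(
            "dissipative_downhill", t,
            f"dG_R = {f.delta_G_R:.1f} kJ/mol below {t.downhill:.0f}",
        )
    if f.reverse_barrier < t.unstable_reverse:
        return ProfileClass(
            "unstable_product", t,
            f"reverse barrier {f.reverse_barrier:.1f} kJ/mol below "
            f"{t.unstable_reverse:.0f}",
        )
    if f.forward_barrier <= t.plausible_barrier and abs(f.delta_G_R) < t.plausible_dgr:
        return ProfileClass(
            "plausible", t,
            f"forward barrier {f.forward_barrier:.1f} <= {t.plausible_barrier:.0f} "
            f"and |dG_R| {abs(f.delta_G_R):.1f} < {t.plausible_dgr:.0f}",
        )
    # total-function fallback: marginal profiles resolve to the leaning side
    if f.delta_G_R <= -t.plausible_dgr:
        return ProfileClass(
            "dissipative_downhill", t,
            f"marginal: dG_R {f.delta_G_R:.1f} kJ/mol beyond the thermoneutral band",
        )
    return ProfileClass(
        "infeasible_uphill", t,
        f"marginal: barrier {f.forward_barrier:.1f} / dG_R {f.delta_G_R:+.1f} kJ/mol "
        "beyond the plausible band",
    )


# ---------------------------------------------------------------------------
# trajectory-level hop analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HopEvent:
    frame: int
    from_site: str
    to_site: str
    species: str = ""  # e.g. hydronium-like


def locate_excess_proton(
    topology: SystemTopology, positions: np.ndarray | None = None
) -> tuple[int, str]:
    """Site currently holding the excess proton, by proton-count bookkeeping.

    Each mobile hydrogen is assigned to the nearest protonable heavy atom;
    the site whose proton count exceeds its reference count holds the
    excess.  A water owning three protons is tagged hydronium-like.  Ties
    (two over-counted sites) are broken by the smaller maximum H-X distance.
    Returns ``(site_id, species_tag)``.
    """
    pos = topology.positions() if positions is None else np.asarray(positions, float)
    h_ids = topology.mobile_proton_ids()
    if not h_ids:
        raise ValueError("no mobile protons defined")
    heavy = [(s, aid) for s in topology.sites for aid in s.heavy_atom_ids]
    heavy_pos = np.array([pos[topology.index_of(aid)] for _, aid in heavy])

    counts: dict[int, int] = {s.site_id: 0 for s in topology.sites}
    maxdist: dict[int, float] = {s.site_id: 0.0 for s in topology.sites}
    for hid in h_ids:
        d = np.linalg.norm(heavy_pos - pos[topology.index_of(hid)], axis=1)
        j = int(np.argmin(d))
        sid = heavy[j][0].site_id
        counts[sid] += 1
        maxdist[sid] = max(maxdist[sid], float(d[j]))

    over = [s for s in topology.sites if counts[s.site_id] > s.reference_proton_count]
    if not over:
        raise ValueError("no excess proton: all sites at their reference proton count")
    holder = min(over, key=lambda s: maxdist[s.site_id])
    if holder.role == "water" and counts[holder.site_id] >= 3:
        tag = "hydronium-like"
    else:
        tag = "protonated"
    if len(over) > 1:
        tag += "|ambiguous"  # two over-counted sites; closest-proton tie-break
    return holder.site_id, tag


def hop_sequence(
    topology: SystemTopology,
    trajectory: np.ndarray,
    min_residence: int = 10,
) -> list[HopEvent]:
    """Debounced Grotthuss hop events along a trajectory of frames.

    The holder site is tracked frame by frame; a transition is emitted only
    once the new holder persists for *min_residence* saved frames, so
    sub-residence flicker across a shared proton produces no event.
    """
    frames = np.asarray(trajectory, float)
    if frames.ndim != 3 or len(frames) < 2:
        raise ValueError("need a trajectory of at least two frames")
    events: list[HopEvent] = []
    current: int | None = None
    pending: int | None = None
    pending_since = 0
    pending_tag = ""
    for t, frame in enumerate(frames):
        sid, tag = locate_excess_proton(topology, frame)
        if current is None:
            current = sid
            continue
        if sid == current:
            pending = None
            continue
        if pending != sid:
            pending, pending_since, pending_tag = sid, t, tag
        if t - pending_since + 1 >= min_residence:
            events.append(
                HopEvent(
                    frame=pending_since,
                    from_site=topology.site(current).name,
                    to_site=topology.site(sid).name,
                    species=pending_tag,
                )
            )
            current, pending = sid, None
    return events
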