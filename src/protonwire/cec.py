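"""Modified center of excess charge (mCEC) and the relative coordinate zeta.

The excess-proton position is tracked by the smooth collective point

    eps = sum_i r_Hi - sum_j w_j r_Xj + sum_i sum_j f_sw(d_ij) (r_Xj - r_Hi)

where i runs over the mobile protons, j over the protonable heavy atoms with
weights w_j, and f_sw is a logistic switching function of the H-X distance,

    f_sw(d) = 1 / (1 + exp((d - r_sw) / d_sw)),

with r_sw = 1.20 A and d_sw = 0.04 A by default.  The correction term snaps
eps onto whichever heavy atom currently holds the excess proton, making the
point follow Grotthuss hopping smoothly across many carriers.

For biased sampling the 3-D point is reduced to the relative transfer
coordinate

    zeta = d_eD / (d_eD + d_eA)  in [0, 1],

the normalized distance ratio between eps and the donor (zeta = 0, reactant)
and acceptor (zeta = 1, product) atoms.  Analytic gradients of zeta with
respect to every atom position are provided for umbrella biasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import SystemTopology

__all__ = [
    "MCECParams",
    "CECValue",
    "switching_value",
    "switching_derivative",
    "compute_mcec",
    "compute_zeta",
    "zeta_gradient",
    "CECEvaluator",
]

_EXP_CLAMP = 500.0


@dataclass(frozen=True)
class MCECParams:
    """Switching-function parameters of the mCEC, in angstrom."""

    r_sw: float = 1.20
    d_sw: float = 0.04

    def __post_init__(self):
        if self.r_sw <= 0 or self.d_sw <= 0:
            raise ValueError("r_sw and d_sw must be positive")


@dataclass
class CECValue:
    """mCEC evaluation at one frame: the eps point, zeta and its gradient."""

    epsilon: np.ndarray
    zeta: float | None = None
    d_eD: float | None = None
    d_eA: float | None = None
    gradient: np.ndarray | None = None  # (n_atoms, 3), d zeta / d r


def switching_value(d, params: MCECParams = MCECParams()):
    """Logistic switching function f_sw(d); smooth, strictly decreasing.

    Evaluated as (1 - tanh(x/2))/2 with x = (d - r_sw)/d_sw, which saturates
    to 1 at covalent distances and to 0 beyond the H-bond range without
    overflow at any distance.
    """
    d = np.asarray(d, dtype=float)
    out = 0.5 * (1.0 - np.tanh(0.5 * (d - params.r_sw) / params.d_sw))
    return float(out) if out.ndim == 0 else out


def switching_derivative(d, params: MCECParams = MCECParams()):
    """d f_sw / d d = -f (1 - f) / d_sw."""
    f = switching_value(d, params)
    return -f * (1.0 - f) / params.d_sw


class CECEvaluator:
    """Pre-indexed mCEC/zeta evaluator for repeated per-frame evaluation.

    Extracts the mobile-proton indices, weighted heavy-atom indices and the
    donor/acceptor indices from the topology once, then evaluates eps, zeta
    and the analytic gradient from a raw (n_atoms, 3) position array.
    """

    def __init__(self, topology: SystemTopology, params: MCECParams = MCECParams()):
        self.params = params
        self.h_idx = np.array(
            [topology.index_of(i) for i in topology.mobile_proton_ids()], dtype=int
        )
        self.x_idx, self.weights = topology.heavy_atom_weights()
        if self.h_idx.size == 0:
            raise ValueError("no excess-charge carriers: topology has no mobile protons")
        if self.x_idx.size == 0:
            raise ValueError("no weighted heavy atoms: topology has no protonable sites")
        self.donor = topology.index_of(topology.donor_atom_id)
        self.acceptor = topology.index_of(topology.acceptor_atom_id)
        self.n_atoms = topology.n_atoms

    # -- eps ---------------------------------------------------------------
    def epsilon(self, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions, dtype=float)
        rH = positions[self.h_idx]          # (nH, 3)
        rX = positions[self.x_idx]          # (nX, 3)
        diff = rX[None, :, :] - rH[:, None, :]      # (nH, nX, 3)
        d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        f = switching_value(d, self.params)
        eps = rH.sum(axis=0) - self.weights @ rX + np.einsum("ij,ijk->k", f, diff)
        return eps

    def evaluate(self, positions: np.ndarray, gradient: bool = False) -> CECValue:
        """eps, zeta and (optionally) the analytic d zeta / d r array."""
        rH = positions[self.h_idx]
        rX = positions[self.x_idx]
        diff = rX[None, :, :] - rH[:, None, :]
        d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        f = 0.5 * (1.0 - np.tanh((0.5 / self.params.d_sw) * (d - self.params.r_sw)))
        eps = rH.sum(axis=0) - self.weights @ rX + np.einsum("ij,ijk->k", f, diff)

        rD = positions[self.donor]
        rA = positions[self.acceptor]
        vD = eps - rD
        vA = eps - rA
        dD = float(np.sqrt(vD @ vD))
        dA = float(np.sqrt(vA @ vA))
        if dD + dA < 1e-12 or np.array_equal(rD, rA):
            raise ValueError("donor and acceptor geometry degenerate (coincident)")
        zeta = dD / (dD + dA)
        out = CECValue(epsilon=eps, zeta=zeta, d_eD=dD, d_eA=dA)
        if not gradient:
            return out

        S2 = (dD + dA) ** 2
        nD = vD / dD if dD > 1e-12 else np.zeros(3)
        nA = vA / dA if dA > 1e-12 else np.zeros(3)
        # d zeta / d eps, holding donor/acceptor fixed
        g_eps = (dA * nD - dD * nA) / S2

        grad = np.zeros((self.n_atoms, 3))
        # direct donor/acceptor dependence of the distance ratio
        grad[self.donor] -= (dA / S2) * nD
        grad[self.acceptor] += (dD / S2) * nA

        # chain rule through eps:
        #   d eps / d rH_i = I (1 - sum_j f_ij) - sum_j f'_ij (rX_j - rH_i) (x) u_ij
        #   d eps / d rX_j = I (sum_i f_ij - w_j) + sum_i f'_ij (rX_j - rH_i) (x) u_ij
        # with u_ij the unit vector from H_i to X_j; each contributes
        # (d eps/d r)^T g_eps to the gradient row of that atom.
        u = diff / np.maximum(d, 1e-12)[:, :, None]
        fp = -f * (1.0 - f) / self.params.d_sw          # (nH, nX)
        # scalar projection of g_eps on the outer-product direction
        coefs = fp * np.einsum("ijk,k->ij", diff, g_eps)
        hin = (1.0 - f.sum(axis=1))[:, None] * g_eps[None, :] \
            - np.einsum("ij,ijk->ik", coefs, u)
        xin = (f.sum(axis=0) - self.weights)[:, None] * g_eps[None, :] \
            + np.einsum("ij,ijk->jk", coefs, u)
        grad[self.h_idx] += hin
        grad[self.x_idx] += xin
        out.gradient = grad
        return out


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def compute_mcec(
    topology: SystemTopology, positions: np.ndarray, params: MCECParams = MCECParams()
) -> CECValue:
    """The eps point only (no donor/acceptor reduction)."""
    ev = CECEvaluator(topology, params)
    return CECValue(epsilon=ev.epsilon(positions))


def compute_zeta(
    topology: SystemTopology, positions: np.ndarray, params: MCECParams = MCECParams()
) -> CECValue:
    return CECEvaluator(topology, params).evaluate(positions, gradient=False)


def zeta_gradient(
    topology: SystemTopology, positions: np.ndarray, params: MCECParams = MCECParams()
) -> np.ndarray:
    """Analytic d zeta / d r, shape (n_atoms, 3); rows sum to ~0."""
    return CECEvaluator(topology, params).evaluate(positions, gradient=True).gradient
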