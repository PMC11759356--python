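"""Forward SAPM model and fitting engine.

Model
-----
Each region's input signaling (proportional to its BOLD response) is the
weighted sum of the output signaling of its afferent connections::

    S_input = M_input @ S_output_ext

where ``M_input`` holds the nonnegative D values (input fractions, summing to
1 over each region's incoming connections) and ``S_output_ext`` stacks the
output signaling of network regions and of latent (external) sources.  Output
signaling obeys the self-consistent fixed point driven by latent inputs::

    (I - M_output) @ S_output = L_out @ latents

where ``M_output`` holds the DB values (D x B; B is the signed factor
converting input signal into output contribution — positive excitatory,
negative inhibitory) on network edges and ``L_out`` the DB values of latent
edges.  The solve is exact; it requires the spectral radius of ``M_output`` to
be below 1 (dissipative network).

Identifiability
---------------
D and B are not separately identifiable from time series alone.  D is fixed by
the normalization constraint — an equal split over each region's incoming
connections — and B (per edge, signed) plus the latent time courses are the
free parameters.  DB = D*B is the reported connectivity statistic.

Fitting
-------
The objective sum_regions sum_time (observed - S_input)^2 is minimized by an
alternating scheme: given B, the latent time courses solve a linear
least-squares problem exactly; given the latents, B is moved by quasi-Newton
gradient steps.  The latent step is fused into every objective evaluation
(variable projection), so the analytic gradient of the profiled objective in B
equals the partial gradient at the optimal latents (envelope theorem).
Multiple random restarts guard against local minima; the best objective wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from sapm.network import NetworkModel

__all__ = [
    "FitConfig",
    "SAPMMatrices",
    "SAPMParameters",
    "SingularNetworkError",
    "build_matrices",
    "default_D",
    "solve_forward",
    "fit_sapm",
    "fit_quality",
    "spectral_radius",
]

#: spectral-radius guard: above this the fixed point is treated as unstable
RHO_MAX = 0.97


class SingularNetworkError(ValueError):
    """(I - M_output) is singular or near-singular; names the spectral radius."""


@dataclass
class FitConfig:
    """Configuration of the SAPM fit.

    n_restarts : random initializations of B (best objective kept).
    max_iterations : cap on gradient iterations per restart.
    tol : relative objective-change convergence tolerance.
    seed : RNG seed for the restarts (full determinism).
    per_run : fit each run separately instead of the run-averaged time course
        per participant/condition (the default target).
    init_scale : s.d. of the random B initialization.
    ridge : gauge-fixing penalty on B, relative to the data sum of squares.
        Low-rank latent dynamics leave some weight combinations
        observationally equivalent (model output is exactly invariant along
        them); the ridge selects the minimal-norm representative of that
        class, making the reported solution unique and reproducible.
    b_max : box bound on |B|; keeps weakly constrained conversion factors in
        a physiologically plausible range (noise-only fits otherwise produce
        rare extreme values).
    """

    n_restarts: int = 5
    max_iterations: int = 500
    tol: float = 1e-6
    seed: int = 0
    per_run: bool = False
    init_scale: float = 0.3
    ridge: float = 1e-5
    b_max: float = 3.0

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class SAPMMatrices:
    """Dense matrix forms of the network parameters.

    M_input, M_output : (R, R), zero diagonal, entries at [target, source].
    D_latent, L_output : (R, L) latent-edge D and DB blocks.
    """

    M_input: np.ndarray
    M_output: np.ndarray
    D_latent: np.ndarray
    L_output: np.ndarray


@dataclass
class SAPMParameters:
    """Fitted SAPM parameters and diagnostics.

    D, B, DB are indexed by the network's canonical connection order
    (edges then latent edges).  ``DB = D * B`` elementwise.
    """

    network: NetworkModel
    D: np.ndarray
    B: np.ndarray
    DB: np.ndarray
    latent_timecourses: np.ndarray
    S_output: np.ndarray
    S_input: np.ndarray
    fit_error: float
    R2: np.ndarray
    trajectory: list = field(default_factory=list)
    converged: bool = True

    def connection_table(self) -> pd.DataFrame:
        """Long-format table: connection, D, B, DB."""
        conns = [f"{s}->{t}" for s, t in self.network.connections]
        return pd.DataFrame({"connection": conns, "D": self.D, "B": self.B, "DB": self.DB})


def default_D(net: NetworkModel) -> np.ndarray:
    """Equal-split D values: 1 / (number of incoming connections of target),
    aligned with ``net.connections``; sums to 1 per region by construction."""
    n_in = {r: len(net.incoming(r)) for r in net.regions}
    return np.array([1.0 / n_in[t] for _, t in net.connections])


def build_matrices(net: NetworkModel, D: np.ndarray, B: np.ndarray) -> SAPMMatrices:
    """Place per-connection D and DB values into dense matrices.

    ``D`` and ``B`` are vectors aligned with ``net.connections`` (network
    edges first, then latent edges).
    """
    D = np.asarray(D, float)
    B = np.asarray(B, float)
    n_conn = len(net.connections)
    if D.shape != (n_conn,) or B.shape != (n_conn,):
        raise ValueError(
            f"parameter vectors must have length {n_conn} "
            f"(got D {D.shape}, B {B.shape}) aligned with net.connections"
        )
    R, L = net.n_regions, net.n_latents
    ridx = {r: i for i, r in enumerate(net.regions)}
    lidx = {ln: j for j, (ln, _) in enumerate(net.latents)}
    M_input = np.zeros((R, R))
    M_output = np.zeros((R, R))
    D_latent = np.zeros((R, L))
    L_output = np.zeros((R, L))
    n_edges = len(net.edges)
    for k, (s, t) in enumerate(net.edges):
        M_input[ridx[t], ridx[s]] = D[k]
        M_output[ridx[t], ridx[s]] = D[k] * B[k]
    for k, (ln, t) in enumerate(net.latents):
        D_latent[ridx[t], lidx[ln]] = D[n_edges + k]
        L_output[ridx[t], lidx[ln]] = D[n_edges + k] * B[n_edges + k]
    return SAPMMatrices(M_input=M_input, M_output=M_output, D_latent=D_latent, L_output=L_output)


def spectral_radius(M: np.ndarray) -> float:
    if M.size == 0:
        return 0.0
    return float(np.abs(np.linalg.eigvals(M)).max())


def solve_forward(
    mats: SAPMMatrices, latents: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact latent-driven fixed-point solve.

    Returns ``(S_output, S_input)`` with
    ``S_output = (I - M_output)^-1 @ (L_output @ latents)`` and
    ``S_input = M_input @ S_output + D_latent @ latents``.
    """
    latents = np.atleast_2d(np.asarray(latents, float))
    R = mats.M_output.shape[0]
    rho = spectral_radius(mats.M_output)
    if rho >= 1.0:
        raise SingularNetworkError(
            f"(I - M_output) is singular/unstable: spectral radius {rho:.4f} >= 1"
        )
    S_output = np.linalg.solve(np.eye(R) - mats.M_output, mats.L_output @ latents)
    S_input = mats.M_input @ S_output + mats.D_latent @ latents
    return S_output, S_input


# ---------------------------------------------------------------------------
# fitting engine
# ---------------------------------------------------------------------------


def _solve_latents(A: np.ndarray, obs: np.ndarray, bases: list) -> np.ndarray:
    """Least-squares latent coefficients given the mixing columns ``A``.

    The model is obs ~ sum_j outer(A[:, j], basis_j @ theta_j); all theta are
    solved jointly (linear).  Returns the (L, T) latent matrix.
    """
    R, T = obs.shape
    L = len(bases)
    cols = []
    for j in range(L):
        Bj = bases[j]  # (T, p_j)
        cols.append(np.einsum("r,tp->rtp", A[:, j], Bj).reshape(R * T, Bj.shape[1]))
    N = np.concatenate(cols, axis=1)
    theta, *_ = np.linalg.lstsq(N, obs.reshape(R * T), rcond=None)
    lat = np.empty((L, T))
    off = 0
    for j in range(L):
        p = bases[j].shape[1]
        lat[j] = bases[j] @ theta[off : off + p]
        off += p
    return lat


def _profiled_objective(b, obs, net_struct, D, bases, lam=0.0):
    """Objective and analytic gradient in B with latents profiled out.

    ``net_struct`` carries precomputed index arrays; the latent coefficients
    are solved by linear least squares (within the per-latent temporal
    bases) at every evaluation, so by the envelope theorem the gradient of
    the profiled objective equals the partial gradient in B at the optimal
    latents.  Returns (f, grad, extras).
    """
    (R, L, n_edges, edge_t, edge_s, lat_t, lat_l) = net_struct
    W = np.zeros((R, R))
    W[edge_t, edge_s] = D[:n_edges] * b[:n_edges]
    rho = spectral_radius(W)
    if rho >= RHO_MAX:
        # unstable region: large value forces the line search to backtrack
        return 1e12 * (1.0 + rho), np.zeros_like(b), None
    C = np.zeros((R, L))
    C[lat_t, lat_l] = D[n_edges:] * b[n_edges:]
    D_lat = np.zeros((R, L))
    D_lat[lat_t, lat_l] = D[n_edges:]
    M_in = np.zeros((R, R))
    M_in[edge_t, edge_s] = D[:n_edges]

    G = np.linalg.inv(np.eye(R) - W)
    H = M_in @ G
    A = H @ C + D_lat  # (R, L): S_input = A @ latents
    lat = _solve_latents(A, obs, bases)
    E = A @ lat - obs  # residual (R, T)
    f = float(np.sum(E * E))

    S_out = G @ (C @ lat)
    HtE = H.T @ E  # (R, T)
    grad = np.empty_like(b)
    # network edges: df/dB_e = 2 D_e * (H^T E S_out^T)[t_e, s_e]
    M1 = HtE @ S_out.T  # (R, R)
    grad[:n_edges] = 2.0 * D[:n_edges] * M1[edge_t, edge_s]
    # latent edges: df/dB = 2 D * (H^T E lat^T)[t, l]
    M2 = HtE @ lat.T  # (R, L)
    grad[n_edges:] = 2.0 * D[n_edges:] * M2[lat_t, lat_l]
    if lam > 0:
        f = f + lam * float(b @ b)
        grad = grad + 2.0 * lam * b
    return f, grad, (lat, S_out, A, E)


def _net_struct(net: NetworkModel):
    ridx = {r: i for i, r in enumerate(net.regions)}
    lidx = {ln: j for j, (ln, _) in enumerate(net.latents)}
    edge_t = np.array([ridx[t] for _, t in net.edges], int)
    edge_s = np.array([ridx[s] for s, _ in net.edges], int)
    lat_t = np.array([ridx[t] for _, t in net.latents], int)
    lat_l = np.array([lidx[ln] for ln, _ in net.latents], int)
    return (net.n_regions, net.n_latents, len(net.edges), edge_t, edge_s, lat_t, lat_l)


def fit_sapm(
    timecourses,
    net: NetworkModel,
    cfg: FitConfig | None = None,
    paradigm=None,
    latent_basis: list | None = None,
    init_B=None,
) -> SAPMParameters:
    """Fit D, B, DB and latent time courses to observed region time courses.

    Parameters
    ----------
    timecourses : (n_regions, n_time) array ordered like ``net.regions``
        (one chosen sub-region per region), in percent signal change, or a
        mapping region -> 1-D time course.
    net : the network model.
    cfg : :class:`FitConfig`; defaults applied when omitted.
    paradigm : :class:`~sapm.design.ParadigmSpec` used to build the latent
        temporal bases when ``latent_basis`` is not supplied; when both are
        omitted a paradigm matching the data length at the default TR is
        assumed.
    latent_basis : list of (T, p_j) per-latent basis matrices (see
        :mod:`sapm.design`); overrides ``paradigm``.

    Returns
    -------
    :class:`SAPMParameters` with the best-restart solution, the per-iteration
    objective trajectory (non-increasing), and per-region R^2.
    """
    from sapm.design import ParadigmSpec, build_latent_basis

    cfg = cfg or FitConfig()
    if isinstance(timecourses, dict):
        obs = np.asarray([timecourses[r] for r in net.regions], float)
    else:
        obs = np.asarray(timecourses, float)
    if obs.ndim != 2 or obs.shape[0] != net.n_regions:
        raise ValueError(
            f"expected a ({net.n_regions}, T) time-course matrix ordered like net.regions, "
            f"got shape {obs.shape}"
        )
    if not np.all(np.isfinite(obs)):
        raise ValueError("time courses contain non-finite values")
    n_free = len(net.connections)
    if obs.shape[1] < 3 * n_free / max(net.n_regions, 1):
        warnings.warn("time course shorter than 3x free parameters per region", stacklevel=2)
    # standardize to mean zero per region (percent-signal-change convention)
    obs = obs - obs.mean(axis=1, keepdims=True)

    if latent_basis is None:
        if paradigm is None:
            # generic fallback: the default paradigm proportions scaled to
            # the data length (TR 1 s)
            T = float(obs.shape[1])
            paradigm = ParadigmSpec(
                TR=1.0,
                run_duration=T,
                inform_time=T * 2 / 9,
                stimulus_onset=T * 4 / 9,
                onset_interval=T / 90,
                contact_duration=T / 180,
                condition="Pain",
            )
        latent_basis = build_latent_basis(paradigm, net.n_latents)
    for j, Bj in enumerate(latent_basis):
        if Bj.shape[0] != obs.shape[1]:
            raise ValueError(
                f"latent basis {j} has {Bj.shape[0]} rows but data have "
                f"{obs.shape[1]} volumes"
            )

    D = default_D(net)
    struct = _net_struct(net)
    rng = np.random.default_rng(cfg.seed)
    lam = cfg.ridge * float(np.sum(obs**2))

    best = None
    any_converged = False
    for restart in range(cfg.n_restarts):
        if restart == 0 and init_B is not None:
            b0 = np.asarray(init_B, float).copy()
        else:
            b0 = rng.normal(0.0, cfg.init_scale, size=n_free)
        traj: list[float] = []

        def fun(b):
            f, g, _ = _profiled_objective(b, obs, struct, D, latent_basis, lam)
            return f, g

        def cb(bk):
            f, _, _ = _profiled_objective(bk, obs, struct, D, latent_basis, lam)
            traj.append(f)

        res = minimize(
            fun,
            b0,
            jac=True,
            method="L-BFGS-B",
            callback=cb,
            bounds=[(-cfg.b_max, cfg.b_max)] * n_free,
            options={"maxiter": cfg.max_iterations, "ftol": cfg.tol, "gtol": 1e-10},
        )
        converged = bool(res.success) or res.status == 0
        any_converged = any_converged or converged
        if best is None or res.fun < best[0]:
            best = (float(res.fun), res.x.copy(), traj, converged)

    f_best, b_best, traj, conv = best
    if not any_converged:
        warnings.warn("no restart converged; returning best objective found", stacklevel=2)
    f, g, extras = _profiled_objective(b_best, obs, struct, D, latent_basis, lam)
    lat, S_out, A, E = extras
    f = float(np.sum(E * E))  # report the residual sum of squares, sans penalty
    mats = build_matrices(net, D, b_best)
    S_output, S_input = solve_forward(mats, lat)

    ss_tot = np.sum(obs**2, axis=1)
    ss_res = np.sum((obs - S_input) ** 2, axis=1)
    degenerate = ss_tot <= 1e-10 * max(float(ss_tot.max()), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        R2 = np.where(~degenerate, 1.0 - ss_res / ss_tot, np.nan)

    return SAPMParameters(
        network=net,
        D=D,
        B=b_best,
        DB=D * b_best,
        latent_timecourses=lat,
        S_output=S_output,
        S_input=S_input,
        fit_error=float(f),
        R2=R2,
        trajectory=traj,
        converged=conv,
    )


def fit_quality(params: SAPMParameters, timecourses) -> pd.DataFrame:
    """Per-region R^2 table: R2_r = 1 - SS_resid_r / SS_tot_r.

    Zero-variance regions get R2 = NaN and ``flagged`` = True.
    """
    net = params.network
    if isinstance(timecourses, dict):
        obs = np.asarray([timecourses[r] for r in net.regions], float)
    else:
        obs = np.asarray(timecourses, float)
    obs = obs - obs.mean(axis=1, keepdims=True)
    ss_tot = np.sum(obs**2, axis=1)
    ss_res = np.sum((obs - params.S_input) ** 2, axis=1)
    degenerate = ss_tot <= 1e-10 * max(float(ss_tot.max()), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(~degenerate, 1.0 - ss_res / ss_tot, np.nan)
    return pd.DataFrame(
        {"region": list(net.regions), "R2": r2, "flagged": degenerate}
    )
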