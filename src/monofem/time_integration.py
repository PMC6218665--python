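"""Time integration: semi-implicit stepper and fully-implicit comparator.

The semi-implicit (IMEX) scheme evaluates diffusion at ``t_{n+1}`` and
reaction at ``t_n``; each step is one reuse of the factorized condensed
matrix, an element-level recovery of the incompatible-mode coefficients,
and a forward-Euler gating update at quadrature points:

    1. assemble b_n from (u_n, alpha_n, r_n) and the stimuli at t_n
    2. u_{n+1}  = -A^{-1} b_n                (stored factorization)
    3. alpha_{n+1} = K_alpha^{-1} p_alpha - K_alpha^{-1} L u_{n+1}
    4. r_{n+1}  = r_n + dt g(u_n^h + alpha_n^h, r_n)

The fully-implicit (FI) comparator is a backward-Euler update solved by
Newton's method with the analytic reaction Jacobian.  The incompatible
coefficients stay explicit unknowns in the monolithic Newton system —
the element-level condensation is derived for the linear semi-implicit
update and does not carry over once the reaction at ``t_{n+1}`` couples
alpha nonlinearly.  Gating is staggered: at each Newton iterate the
backward-Euler gating equation is re-solved per quadrature point for the
current potential iterate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import ionic
from .assembly import Conductivity, State, SystemOperators, assemble_system
from .elements import ElementFamily, get_family
from .mesh import Mesh

__all__ = ["SchemeConfig", "StimulusSampler", "RunResult",
           "si_step", "recover_alpha", "FullImplicitOperators", "fi_step", "run"]


@dataclass(frozen=True)
class SchemeConfig:
    """Time-stepping configuration (times in ms)."""

    scheme: str = "SI"                  # "SI" or "FI"
    dt: float = 0.001
    t_end: float = 100.0
    newton_tol: float = 1e-10           # FI only: inf-norm of the Newton update
    newton_max_iter: int = 25
    snapshot_every_ms: float | None = None

    def __post_init__(self) -> None:
        if self.scheme not in ("SI", "FI"):
            raise ValueError("scheme must be 'SI' or 'FI'")
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")
        if self.newton_tol <= 0 or self.newton_max_iter < 1:
            raise ValueError("Newton settings must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))


class StimulusSampler:
    """Precomputed quadrature-point masks / boundary loads for stimuli.

    Volume stimuli add their normalized amplitude (1/ms) to the reaction
    integrand at every quadrature point inside their region; surface
    stimuli contribute an injected-current boundary load
    ``amplitude * int N_a ds`` over the faces of their face set.
    A stimulus is active for ``start <= t < start + duration``.
    """

    def __init__(self, stimuli, ops: SystemOperators):
        self._volume = []      # (mask (nel, nq), amplitude, t0, t1)
        self._surface = []     # (load (nn,), t0, t1)
        mesh = ops.mesh
        flat = ops.qp_coords.reshape(-1, 3)
        for stim in stimuli or ():
            t0, t1 = stim.start, stim.start + stim.duration
            if stim.kind == "volume":
                mask = stim.region.contains(flat).reshape(ops.qp_coords.shape[:2])
                if not mask.any():
                    raise ValueError(f"volume stimulus region {stim.region} contains "
                                     "no quadrature points")
                self._volume.append((mask, stim.amplitude, t0, t1))
            elif stim.kind == "surface":
                load = _face_load_vector(mesh, ops, stim.face_set) * stim.amplitude
                self._surface.append((load, t0, t1))
            else:
                raise ValueError(f"unknown stimulus kind {stim.kind!r}")

    def volume_qp(self, t: float) -> np.ndarray | None:
        out = None
        for mask, amp, t0, t1 in self._volume:
            if t0 <= t < t1:
                if out is None:
                    out = np.zeros(mask.shape)
                out[mask] += amp
        return out

    def surface_load(self, t: float) -> np.ndarray | None:
        out = None
        for load, t0, t1 in self._surface:
            if t0 <= t < t1:
                out = load if out is None else out + load
        return out


def _face_load_vector(mesh: Mesh, ops: SystemOperators, face_set: str) -> np.ndarray:
    """Assemble ``int_F N_a ds`` over all faces of a named face set."""
    from .elements import eval_q1_basis, eval_q2_basis
    from .mesh import _FACE_KEYS
    if face_set not in mesh.face_sets:
        raise KeyError(f"face set {face_set!r} not in mesh (has {sorted(mesh.face_sets)})")
    fam = ops.family
    k = fam.quad_points_per_axis
    x1, w1 = np.polynomial.legendre.leggauss(k)
    evalf = eval_q2_basis if fam.name == "Q2" else eval_q1_basis
    load = np.zeros(mesh.n_nodes)
    corner_elems = mesh.corner_elems()
    for elem, fid in mesh.face_sets[face_set]:
        ax, side = _FACE_KEYS[int(fid)]
        t_axes = [a for a in range(3) if a != ax]
        coords = mesh.nodes[corner_elems[int(elem)]]
        conn = mesh.elems[int(elem)]
        for i, s in enumerate(x1):
            for j, t in enumerate(x1):
                xi = np.zeros(3)
                xi[ax] = float(side)
                xi[t_axes[0]], xi[t_axes[1]] = s, t
                Nf, _ = evalf(xi)
                _, dNg = eval_q1_basis(xi)
                J = coords.T @ dNg                      # trilinear geometry map
                dA = np.linalg.norm(np.cross(J[:, t_axes[0]], J[:, t_axes[1]]))
                np.add.at(load, conn, w1[i] * w1[j] * dA * Nf)
    return load


def si_step(state: State, system: SystemOperators,
            params: ionic.IonicParams = ionic.MODIFIED_AP_PARAMS,
            sampler: StimulusSampler | None = None) -> State:
    """One semi-implicit step; reaction and stimuli evaluated at t_n."""
    dt = system.dt
    t_n = state.time
    phi_qp = system.interpolate_qp(state.u, state.alpha)
    react = phi_qp / dt + ionic.ionic_current(phi_qp, state.r, params)
    if sampler is not None:
        i_app = sampler.volume_qp(t_n)
        if i_app is not None:
            react = react + i_app
        sload = sampler.surface_load(t_n)
    else:
        sload = None
    b, p_alpha = system.assemble_rhs(react, surface_load=sload)
    u_new = system.solve(-b)
    if not np.all(np.isfinite(u_new)):
        raise FloatingPointError(f"non-finite potential after step at t={t_n + dt:.6g} ms")
    alpha_new = system.recover_alpha(u_new, p_alpha)
    r_new = state.r + dt * ionic.gating_rate(phi_qp, state.r, params)
    return State(u=u_new, alpha=alpha_new, r=r_new, time=t_n + dt)


def recover_alpha(u_new_e: np.ndarray, blocks, p_alpha_e: np.ndarray) -> np.ndarray:
    """Element-level recovery ``alpha = K_alpha^{-1}(p_alpha - L u)``.

    Single-element convenience around cached :class:`ElementBlocks`.
    """
    if blocks.K_alpha.shape[0] == 0:
        return np.zeros(0)
    return blocks.K_alpha_inv @ p_alpha_e - blocks.K_alpha_inv_L @ u_new_e


class FullImplicitOperators:
    """Constant blocks and DOF maps for the monolithic backward-Euler system.

    Unknowns are ``z = [u (nn,) ; alpha (3 per element)]``; the constant
    part ``J0 = [[K_u, L^T], [L, K_alpha]]`` is assembled once, the
    reaction Jacobian is re-assembled at each Newton iteration.
    """

    def __init__(self, mesh: Mesh, D: Conductivity, dt: float,
                 family: ElementFamily | str | None = None):
        ops = SystemOperators(mesh, D, dt, family)
        self.ops = ops
        self.mesh, self.dt = mesh, dt
        fam = ops.family
        nel, nen, nnc = mesh.n_elements, fam.nodes_per_element, fam.nc_modes
        nn = mesh.n_nodes
        self.nn, self.nnc = nn, nnc
        self.ndof = nn + nnc * nel
        if nnc:
            adofs = nn + (nnc * np.arange(nel)[:, None] + np.arange(nnc)[None, :])
            self.dofmap = np.hstack([mesh.elems, adofs])
        else:
            self.dofmap = mesh.elems
        nloc = nen + nnc
        J0_e = np.empty((nel, nloc, nloc))
        J0_e[:, :nen, :nen] = ops.K_u
        if nnc:
            J0_e[:, :nen, nen:] = np.swapaxes(ops.L, 1, 2)
            J0_e[:, nen:, :nen] = ops.L
            J0_e[:, nen:, nen:] = ops.K_alpha
        self._rows = np.repeat(self.dofmap, nloc, axis=1).ravel()
        self._cols = np.tile(self.dofmap, (1, nloc)).ravel()
        self.J0 = sp.coo_matrix((J0_e.ravel(), (self._rows, self._cols)),
                                shape=(self.ndof, self.ndof)).tocsc()
        self.B = np.hstack([ops.N, ops.W])       # (nq, nloc)
        self._flat_dofs = self.dofmap.ravel()

    def _split(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        u = z[:self.nn]
        alpha = z[self.nn:].reshape(self.mesh.n_elements, self.nnc) if self.nnc \
            else np.zeros((self.mesh.n_elements, 0))
        return u, alpha

    def residual_and_phi(self, z, state: State, params, sampler, t_new):
        ops = self.ops
        u, alpha = self._split(z)
        phi = ops.interpolate_qp(u, alpha)
        r_new = ionic.gating_step_backward(phi, state.r, self.dt, params)
        phi_old = ops.interpolate_qp(state.u, state.alpha)
        react = phi_old / self.dt + ionic.ionic_current(phi, r_new, params)
        sload = None
        if sampler is not None:
            i_app = sampler.volume_qp(t_new)
            if i_app is not None:
                react = react + i_app
            sload = sampler.surface_load(t_new)
        integ = react * ops.wdet
        p_e = np.einsum("qa,eq->ea", self.B, integ)
        p = np.bincount(self._flat_dofs, weights=p_e.ravel(), minlength=self.ndof)
        if sload is not None:
            p[:self.nn] += sload
        return self.J0 @ z - p, phi, r_new

    def reaction_jacobian(self, phi, r_new, params) -> sp.csc_matrix:
        df = ionic.dionic_dphi(phi, r_new, params) * self.ops.wdet
        blocks = np.einsum("eq,qa,qb->eab", df, self.B, self.B)
        return sp.coo_matrix((blocks.ravel(), (self._rows, self._cols)),
                             shape=(self.ndof, self.ndof)).tocsc()


def fi_step(state: State, fi_ops: FullImplicitOperators,
            params: ionic.IonicParams = ionic.MODIFIED_AP_PARAMS,
            sampler: StimulusSampler | None = None,
            tol: float = 1e-10, max_iter: int = 25) -> State:
    """One backward-Euler step solved by Newton with analytic Jacobian."""
    dt = fi_ops.dt
    t_new = state.time + dt
    z = np.concatenate([state.u, state.alpha.ravel()])
    phi = r_new = None
    for it in range(max_iter):
        R, phi, r_new = fi_ops.residual_and_phi(z, state, params, sampler, t_new)
        Jr = fi_ops.reaction_jacobian(phi, r_new, params)
        dz = spla.spsolve(fi_ops.J0 - Jr, -R)
        z = z + dz
        if not np.all(np.isfinite(z)):
            raise FloatingPointError(f"non-finite Newton iterate at t={t_new:.6g} ms")
        if np.max(np.abs(dz)) < tol:
            break
    else:
        raise RuntimeError(
            f"Newton failed to converge in {max_iter} iterations at t={t_new:.6g} ms "
            f"(last update {np.max(np.abs(dz)):.3e})")
    u, alpha = fi_ops._split(z)
    phi = fi_ops.ops.interpolate_qp(u, alpha)
    r_new = ionic.gating_step_backward(phi, state.r, dt, params)
    return State(u=u, alpha=alpha, r=r_new, time=t_new)


@dataclass
class RunResult:
    """Outputs of a fixed-step simulation."""

    times: np.ndarray                    # (n_rec,) probe-trace sample times, ms
    probe_nodes: np.ndarray              # node indices of the probes
    probe_traces: np.ndarray             # (n_rec, n_probes) normalized potential
    activation: np.ndarray               # (nn,) first phi>threshold times; inf if never
    threshold: float
    state: State                         # final state
    snapshots: list = field(default_factory=list)   # [(t, u.copy()), ...]
    steps_taken: int = 0


def run(mesh: Mesh, family: ElementFamily | str, D: Conductivity,
        params: ionic.IonicParams, scheme: SchemeConfig, stimuli=(),
        probe_points=(), threshold: float = 0.5, stop_when: str = "t_end",
        log_every: int = 0) -> RunResult:
    """Drive the fixed-dt time loop over [0, t_end].

    Records per-step probe traces, the running node-wise activation map
    (first discrete sample with phi > threshold) and optional field
    snapshots.  ``stop_when`` may end the run early once 'probes_activated'
    or 'all_activated' is reached.  Entirely deterministic.
    """
    if stop_when not in ("t_end", "probes_activated", "all_activated"):
        raise ValueError(f"unknown stop_when={stop_when!r}")
    fam = get_family(family) if isinstance(family, str) else family
    if scheme.scheme == "FI":
        fi_ops = FullImplicitOperators(mesh, D, scheme.dt, fam)
        ops = fi_ops.ops
    else:
        fi_ops = None
        ops = assemble_system(mesh, D, scheme.dt, fam)
    sampler = StimulusSampler(stimuli, ops)
    state = ops.initial_state(params)
    probe_nodes = np.array([mesh.nearest_node(p) for p in probe_points], dtype=int)
    act = np.full(mesh.n_nodes, np.inf)
    act[state.u > threshold] = 0.0
    traces = [state.u[probe_nodes].copy()]
    rec_times = [0.0]
    snapshots = []
    snap_every = scheme.snapshot_every_ms
    next_snap = 0.0 if snap_every else None
    n_steps = scheme.n_steps
    step = 0
    for step in range(1, n_steps + 1):
        if scheme.scheme == "SI":
            state = si_step(state, ops, params, sampler)
        else:
            state = fi_step(state, fi_ops, params, sampler,
                            tol=scheme.newton_tol, max_iter=scheme.newton_max_iter)
        fresh = np.isinf(act) & (state.u > threshold)
        if fresh.any():
            act[fresh] = state.time
        traces.append(state.u[probe_nodes].copy())
        rec_times.append(state.time)
        if next_snap is not None and state.time + 1e-12 >= next_snap:
            snapshots.append((state.time, state.u.copy()))
            next_snap += snap_every
        if log_every and step % log_every == 0:
            print(f"  t={state.time:9.3f} ms  max phi={state.u.max():7.4f}")
        if stop_when == "probes_activated" and probe_nodes.size and \
                np.all(np.isfinite(act[probe_nodes])):
            break
        if stop_when == "all_activated" and step % 20 == 0 and \
                np.all(np.isfinite(act)):
            break
    return RunResult(times=np.asarray(rec_times), probe_nodes=probe_nodes,
                     probe_traces=np.asarray(traces), activation=act,
                     threshold=threshold, state=state, snapshots=snapshots,
                     steps_taken=step)
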