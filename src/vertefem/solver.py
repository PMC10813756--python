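"""Quasi-static, displacement-controlled elastoplastic T4 solver.

Small-strain, geometrically linear kinematics with constant-strain
tetrahedra; the material is isotropic elastic with associative J2
(von Mises) perfect plasticity, integrated by the closed-form radial
return.  The uniaxial stress-strain law sigma = E*eps below yield and
sigma = sigma_y beyond is the exact uniaxial specialization of this
model, so homogeneous bar states reproduce it identically.

Boundary conditions are realized by a master-slave transformation
``u = T q + d g``: in follower mode the cranial-surface nodes are rigid
slaves of a control point (linearized rotation, three rotations free,
transverse translations locked), the caudal surface is fully fixed, and
``d`` is the prescribed compression magnitude.  Each increment is solved
by Newton iteration on the reduced residual ``T^T f_int = 0`` with the
algorithmic (consistent) tangent; because the perfectly plastic tangent
is only positive semi-definite, the Newton matrix is regularized by
``+1e-9 K_elastic`` whenever plasticity is active (the converged solution
is unaffected: convergence is judged on the true residual).

The compressive reaction conjugate to ``d`` is ``g^T f_int`` (N); curves
are reported in kN against mm, compression positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .meshing import LoadCase, TetMesh
from .postprocess import LoadDisplacementCurve

NEWTON_TOL_REL = 1e-6
NEWTON_TOL_ABS = 1e-8  # N
NEWTON_MAX_ITER = 25
TANGENT_REG = 1e-9  # elastic-stiffness fraction added to the plastic tangent

_VOIGT_SHEAR_SLICE = slice(3, 6)
# deviatoric projector acting on engineering-shear strain vectors
_IDEV_ENG = np.zeros((6, 6))
_IDEV_ENG[:3, :3] = np.eye(3) - np.ones((3, 3)) / 3.0
_IDEV_ENG[3:, 3:] = np.eye(3) / 2.0
_ONES6 = np.zeros((6, 6))
_ONES6[:3, :3] = 1.0


# ---------------------------------------------------------------------------
# plastic state and the radial-return map
# ---------------------------------------------------------------------------


@dataclass
class PlasticState:
    """Committed plastic strain (engineering Voigt) and equivalent plastic strain."""

    eps_p: np.ndarray  # (n_elems, 6), [exx eyy ezz gxy gyz gxz]
    peeq: np.ndarray  # (n_elems,)

    @classmethod
    def zeros(cls, n_elems: int) -> "PlasticState":
        return cls(eps_p=np.zeros((n_elems, 6)), peeq=np.zeros(n_elems))

    def copy(self) -> "PlasticState":
        return PlasticState(self.eps_p.copy(), self.peeq.copy())


def von_mises(sig: np.ndarray) -> np.ndarray:
    """Von Mises equivalent of Voigt stress rows [sxx syy szz sxy syz sxz]."""
    sig = np.atleast_2d(sig)
    d1 = sig[:, 0] - sig[:, 1]
    d2 = sig[:, 1] - sig[:, 2]
    d3 = sig[:, 2] - sig[:, 0]
    return np.sqrt(0.5 * (d1**2 + d2**2 + d3**2) + 3.0 * (sig[:, 3:] ** 2).sum(axis=1))


def radial_return(trial_stress: np.ndarray, sigma_y: float, shear_modulus: float):
    """Return-map one trial stress tensor onto the von Mises surface.

    Parameters are a symmetric 3x3 trial Cauchy stress (MPa), the yield
    stress and the shear modulus G.  Returns ``(stress, delta_peeq)``:
    below yield the stress is unchanged and delta_peeq = 0; above it the
    deviator is scaled so the von Mises stress equals sigma_y exactly and
    ``delta_peeq = (q_trial - sigma_y) / (3 G)``.  The hydrostatic part is
    never modified (isochoric plastic flow).
    """
    t = np.asarray(trial_stress, dtype=float)
    if t.shape != (3, 3) or not np.allclose(t, t.T, atol=1e-9 * max(1.0, np.abs(t).max())):
        raise ValueError("trial stress must be a symmetric 3x3 tensor")
    if sigma_y <= 0:
        raise ValueError("sigma_y must be > 0")
    p = np.trace(t) / 3.0
    s = t - p * np.eye(3)
    q = np.sqrt(1.5 * np.sum(s * s))
    if q <= sigma_y:
        return t.copy(), 0.0
    return p * np.eye(3) + s * (sigma_y / q), (q - sigma_y) / (3.0 * shear_modulus)


def _stress_update(eps, state: PlasticState, lam, mu, sigma_y):
    """Vectorized elastic predictor / radial-return corrector.

    Takes total engineering strains (m, 6) and the committed state;
    returns stress, the candidate updated state, the plastic mask and the
    trial deviator data needed for the algorithmic tangent.
    """
    e = eps - state.eps_p
    tr = e[:, :3].sum(axis=1)
    sig = np.empty_like(e)
    sig[:, :3] = lam[:, None] * tr[:, None] + 2.0 * mu[:, None] * e[:, :3]
    sig[:, 3:] = mu[:, None] * e[:, 3:]

    p = sig[:, :3].mean(axis=1)
    s = sig.copy()
    s[:, :3] -= p[:, None]
    q = np.sqrt(1.5 * ((s[:, :3] ** 2).sum(axis=1) + 2.0 * (s[:, 3:] ** 2).sum(axis=1)))

    plastic = q > sigma_y
    eps_p_new = state.eps_p.copy()
    peeq_new = state.peeq.copy()
    if plastic.any():
        qp = q[plastic]
        syp = sigma_y[plastic]
        mup = mu[plastic]
        fac = syp / qp
        dgam = (qp - syp) / (3.0 * mup)
        sig_pl = s[plastic] * fac[:, None]
        sig_pl[:, :3] += p[plastic, None]
        sig[plastic] = sig_pl
        # flow direction N = 1.5 s/q; engineering shears accumulate 2x
        flow = 1.5 * s[plastic] / qp[:, None]
        flow[:, 3:] *= 2.0
        eps_p_new[plastic] += dgam[:, None] * flow
        peeq_new[plastic] += dgam
    return sig, PlasticState(eps_p_new, peeq_new), plastic, s, q


def _incremental_energy(eps, state: PlasticState, lam, mu, sigma_y, V) -> float:
    """Convex incremental potential whose gradient is the internal force.

    Per element, with elastic trial deviatoric von Mises q_tr and bulk
    modulus K: the elastic branch stores 0.5*K*tr^2 + q_tr^2/(6G); the
    plastic branch replaces the deviatoric term by the Huber-type
    sigma_y^2/(6G) + sigma_y*(q_tr - sigma_y)/(3G), which is C^1 at yield.
    Line searches are performed on this function: Newton directions on
    the (regularized, positive semi-definite) consistent tangent are
    descent directions for it, which makes the iteration globally
    convergent even at the limit load.
    """
    e = eps - state.eps_p
    tr = e[:, :3].sum(axis=1)
    K_bulk = lam + 2.0 * mu / 3.0
    dev_n = e[:, :3] - tr[:, None] / 3.0
    # tensor norm^2 of the strain deviator; engineering shears contribute g^2/2
    dev2 = (dev_n**2).sum(axis=1) + 0.5 * (e[:, 3:] ** 2).sum(axis=1)
    q_tr = 3.0 * mu * np.sqrt(2.0 * dev2 / 3.0)
    W_dev = np.where(
        q_tr <= sigma_y,
        q_tr**2 / (6.0 * mu),
        sigma_y**2 / (6.0 * mu) + sigma_y * (q_tr - sigma_y) / (3.0 * mu),
    )
    return float(np.sum(V * (0.5 * K_bulk * tr**2 + W_dev)))


def _algorithmic_tangent(De, plastic, s_trial, q_trial, lam, mu, sigma_y):
    """Consistent tangent per element (Voigt, acting on engineering strain).

    Plastic elements get
        D = K 1x1 + (2 G sigma_y / q) I_dev - (3 G sigma_y / q^3) s s^T
    which is the exact linearization of the radial-return stress and
    positive semi-definite (its deviatoric eigenvalue along the flow
    direction is exactly zero).
    """
    D = De.copy()
    if plastic.any():
        K_bulk = lam[plastic] + 2.0 * mu[plastic] / 3.0
        q = q_trial[plastic]
        sy = sigma_y[plastic]
        G = mu[plastic]
        s = s_trial[plastic]  # stress-like Voigt deviator, works on eng. strain
        D_pl = (
            K_bulk[:, None, None] * _ONES6[None]
            + (2.0 * G * sy / q)[:, None, None] * _IDEV_ENG[None]
            - (3.0 * G * sy / q**3)[:, None, None] * np.einsum("ei,ej->eij", s, s)
        )
        D[plastic] = D_pl
    return D


# ---------------------------------------------------------------------------
# element precomputation and assembly
# ---------------------------------------------------------------------------


class ElementData:
    """Precomputed B-matrices, volumes, DOF maps and elastic moduli."""

    def __init__(self, mesh: TetMesh, cards):
        coords = mesh.nodes[mesh.tets]  # (m, 4, 3)
        J = coords[:, 1:] - coords[:, :1]
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            bad = int(np.argmin(detJ))
            raise ValueError(f"inverted element {bad}: volume {detJ[bad] / 6.0:.3e} mm^3")
        self.V = detJ / 6.0
        # grad N_i (i=1..3) are the rows of (J^T)^-1, i.e. columns of J^-1
        invJT = np.transpose(np.linalg.inv(J), (0, 2, 1))
        grads = np.concatenate([-invJT.sum(axis=1, keepdims=True), invJT], axis=1)  # (m,4,3)

        m = len(mesh.tets)
        B = np.zeros((m, 6, 12))
        for a in range(4):
            gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
            c = 3 * a
            B[:, 0, c] = gx
            B[:, 1, c + 1] = gy
            B[:, 2, c + 2] = gz
            B[:, 3, c] = gy
            B[:, 3, c + 1] = gx
            B[:, 4, c + 1] = gz
            B[:, 4, c + 2] = gy
            B[:, 5, c] = gz
            B[:, 5, c + 2] = gx
        self.B = B
        self.dof = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(m, 12)

        E, nu = cards.E, cards.nu
        self.lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        self.mu = E / (2 * (1 + nu))
        self.sigma_y = cards.sigma_y
        De = np.zeros((m, 6, 6))
        De[:, :3, :3] = self.lam[:, None, None] * np.ones((3, 3))[None]
        De[:, :3, :3] += 2.0 * self.mu[:, None, None] * np.eye(3)[None]
        De[:, 3:, 3:] = self.mu[:, None, None] * np.eye(3)[None]
        self.De = De
        self.ndof = 3 * mesh.n_nodes

        # precomputed CSR scatter pattern: element stiffness entries sum into
        # data slots directly, skipping the COO sort on every assembly
        rows = np.broadcast_to(self.dof[:, :, None], (m, 12, 12)).ravel()
        cols = np.broadcast_to(self.dof[:, None, :], (m, 12, 12)).ravel()
        order = np.lexsort((cols, rows))
        r_s, c_s = rows[order], cols[order]
        new_group = np.empty(len(r_s), dtype=bool)
        new_group[0] = True
        new_group[1:] = (r_s[1:] != r_s[:-1]) | (c_s[1:] != c_s[:-1])
        slot_sorted = np.cumsum(new_group) - 1
        self._slot = np.empty_like(slot_sorted)
        self._slot[order] = slot_sorted
        self._csr_indices = c_s[new_group]
        starts = r_s[new_group]
        self._csr_indptr = np.searchsorted(starts, np.arange(self.ndof + 1))
        self._nnz = int(slot_sorted[-1]) + 1

    def strains(self, u: np.ndarray) -> np.ndarray:
        return np.einsum("eij,ej->ei", self.B, u[self.dof])

    def internal_force(self, sig: np.ndarray) -> np.ndarray:
        f_el = np.einsum("eki,ek->ei", self.B, sig) * self.V[:, None]
        return np.bincount(self.dof.ravel(), weights=f_el.ravel(), minlength=self.ndof)

    def stiffness(self, D: np.ndarray) -> sp.csr_matrix:
        Ke = np.einsum("eki,ekl,elj->eij", self.B, D, self.B) * self.V[:, None, None]
        data = np.bincount(self._slot, weights=Ke.ravel(), minlength=self._nnz)
        return sp.csr_matrix(
            (data, self._csr_indices, self._csr_indptr), shape=(self.ndof, self.ndof)
        )


def assemble_system(mesh: TetMesh, cards, u=None, state: PlasticState | None = None):
    """Tangent stiffness and internal-force vector at displacement ``u``.

    Convenience entry point (also used by the patch and symmetry tests):
    returns ``(K, f_int, stress)`` with K consistent with the
    radial-return update at ``u`` given the committed ``state``.
    """
    ed = ElementData(mesh, cards)
    if u is None:
        u = np.zeros(ed.ndof)
    if state is None:
        state = PlasticState.zeros(mesh.n_elements)
    eps = ed.strains(u)
    sig, _, plastic, s_tr, q_tr = _stress_update(eps, state, ed.lam, ed.mu, ed.sigma_y)
    D = _algorithmic_tangent(ed.De, plastic, s_tr, q_tr, ed.lam, ed.mu, ed.sigma_y)
    return ed.stiffness(D), ed.internal_force(sig), sig


# ---------------------------------------------------------------------------
# boundary conditions: master-slave transformation u = T q + d g
# ---------------------------------------------------------------------------


def _skew(r: np.ndarray) -> np.ndarray:
    return np.array([[0, -r[2], r[1]], [r[2], 0, -r[0]], [-r[1], r[0], 0.0]])


def _build_transformation(mesh: TetMesh, lc: LoadCase):
    """Sparse T (3n x n_free) and drive vector g with u = T q + d g.

    Follower mode: caudal DOFs zero; cranial node i is a rigid slave,
    u_i = -d*axial + theta x (x_i - cp), with the three rotation
    components theta appended as the last free unknowns.
    Uniaxial mode: cranial axial DOFs driven by -d, caudal axial fixed,
    plus a statically determinate 3-2-1 lateral support on the caudal
    surface so lateral expansion stays free.
    """
    n = mesh.n_nodes
    ndof = 3 * n
    axial = np.asarray(lc.axial_direction, float)
    axial = axial / np.linalg.norm(axial)
    cranial = mesh.node_sets[lc.coupled_set]
    caudal = mesh.node_sets[lc.fixed_set]
    g = np.zeros(ndof)

    rows, cols, vals = [], [], []
    if lc.mode == "follower":
        constrained = np.zeros(n, dtype=bool)
        constrained[cranial] = True
        constrained[caudal] = True
        free_nodes = np.nonzero(~constrained)[0]
        nq = 3 * len(free_nodes) + 3
        # identity block for unconstrained nodes
        r_id = (3 * free_nodes[:, None] + np.arange(3)).ravel()
        rows.append(r_id)
        cols.append(np.arange(3 * len(free_nodes)))
        vals.append(np.ones(3 * len(free_nodes)))
        # rigid-coupling block: u_i = theta x r_i = -skew(r_i) theta
        th0 = 3 * len(free_nodes)
        for i in cranial:
            r = mesh.nodes[i] - lc.control_point
            S = -_skew(r)
            rr, cc = np.meshgrid(3 * i + np.arange(3), th0 + np.arange(3), indexing="ij")
            rows.append(rr.ravel())
            cols.append(cc.ravel())
            vals.append(S.ravel())
            g[3 * i : 3 * i + 3] = -axial
        theta_cols = (th0, th0 + 3)
    elif lc.mode == "uniaxial":
        free = np.ones(ndof, dtype=bool)
        free[3 * cranial + 2] = False
        free[3 * caudal + 2] = False
        g[3 * cranial + 2] = -1.0
        # 3-2-1 lateral supports on the caudal surface (exact for the
        # uniform uniaxial field centered at node A)
        pts = mesh.nodes[caudal]
        order = np.lexsort((pts[:, 0], pts[:, 1]))
        A = caudal[order[0]]
        same_row = caudal[np.abs(mesh.nodes[caudal][:, 1] - mesh.nodes[A][1]) < 1e-9]
        B = same_row[np.argmax(mesh.nodes[same_row][:, 0])]
        if B == A:
            raise ValueError("cannot build determinate lateral supports (degenerate base)")
        free[3 * A] = False
        free[3 * A + 1] = False
        free[3 * B + 1] = False
        free_idx = np.nonzero(free)[0]
        nq = len(free_idx)
        rows.append(free_idx)
        cols.append(np.arange(nq))
        vals.append(np.ones(nq))
        theta_cols = None
    else:  # pragma: no cover - guarded by LoadCase.validate
        raise ValueError(lc.mode)

    T = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, nq),
    ).tocsr()
    return T, g, theta_cols


# ---------------------------------------------------------------------------
# quasi-static solve
# ---------------------------------------------------------------------------


@dataclass
class SolutionRecord:
    """Per-increment history of a displacement-controlled solve."""

    displacement: np.ndarray  # prescribed compression magnitudes, mm (starts at 0)
    reaction_N: np.ndarray  # compressive reaction, N
    curve: LoadDisplacementCurve  # same data in mm / kN
    peeq_history: list  # per increment: (n_elems,) PEEQ
    rotation_history: list  # per increment: (3,) control-point rotation, rad
    displacement_fields: list  # per increment: (3n,) nodal displacements
    converged: bool = True
    n_increments_completed: int = 0
    message: str = ""
    final_state: PlasticState | None = None


def solve_quasistatic(
    mesh: TetMesh,
    cards,
    loadcase: LoadCase,
    tol_rel: float = NEWTON_TOL_REL,
    tol_abs: float = NEWTON_TOL_ABS,
    max_iter: int = NEWTON_MAX_ITER,
    record_fields: bool = True,
) -> SolutionRecord:
    """Run the displacement-controlled elastoplastic solve.

    The prescribed compression grows linearly over ``n_increments`` equal
    steps; each step is equilibrated by Newton iteration with the
    consistent tangent and closed-form radial-return state update.  On
    Newton failure the record of all converged increments is returned
    with ``converged=False`` and an explanatory message.
    """
    loadcase.validate(mesh)
    mesh.validate()
    ed = ElementData(mesh, cards)
    T, g, theta_cols = _build_transformation(mesh, loadcase)
    if T.shape[1] == 0:
        raise ValueError("load case leaves no free degrees of freedom")
    Tc = T.T.tocsr()
    K_e_red = (Tc @ ed.stiffness(ed.De) @ T).tocsc()

    state = PlasticState.zeros(mesh.n_elements)
    q = np.zeros(T.shape[1])
    N = loadcase.n_increments
    d_steps = loadcase.total_displacement * np.arange(N + 1) / N

    disp = [0.0]
    reac = [0.0]
    peeq_hist = [state.peeq.copy()]
    rot_hist = [np.zeros(3)]
    fields = [np.zeros(3 * mesh.n_nodes)] if record_fields else []
    converged = True
    msg = ""
    completed = 0

    def newton(q0, committed: PlasticState, d: float):
        """Equilibrate at prescribed compression d from the committed state.

        Newton on the consistent tangent with Armijo backtracking on the
        convex incremental energy (the regularized tangent is SPD, so the
        Newton direction always descends).  Returns (ok, q, data).
        """

        def evaluate(q_try):
            u = T @ q_try + d * g
            eps = ed.strains(u)
            sig, new_state, plastic, s_tr, q_tr = _stress_update(
                eps, committed, ed.lam, ed.mu, ed.sigma_y
            )
            f_int = ed.internal_force(sig)
            res = Tc @ f_int
            energy = _incremental_energy(eps, committed, ed.lam, ed.mu, ed.sigma_y, ed.V)
            return res, energy, f_int, sig, new_state, plastic, s_tr, q_tr, u

        q_it = q0
        res, energy, f_int, sig, new_state, plastic, s_tr, q_tr, u = evaluate(q_it)
        for _ in range(max_iter):
            if np.linalg.norm(res) <= max(tol_rel * np.linalg.norm(f_int), tol_abs):
                return True, q_it, (f_int, new_state, u)
            D = _algorithmic_tangent(ed.De, plastic, s_tr, q_tr, ed.lam, ed.mu, ed.sigma_y)
            K_red = (Tc @ ed.stiffness(D) @ T).tocsc()
            if plastic.any():
                K_red = K_red + TANGENT_REG * K_e_red
            dq = splu(K_red).solve(-res)
            slope = float(res @ dq)
            alpha, accepted = 1.0, False
            for _ls in range(20):
                cand = evaluate(q_it + alpha * dq)
                if cand[1] <= energy + 1e-4 * alpha * slope:
                    q_it = q_it + alpha * dq
                    res, energy, f_int, sig, new_state, plastic, s_tr, q_tr, u = cand
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                break
        return False, q_it, (f_int, new_state, u)

    q_rate = None  # secant dq/dd from the last committed pair, warm-starts increments
    for t in range(1, N + 1):
        d_prev, d = d_steps[t - 1], d_steps[t]
        # automatic cutback: retry a failed increment in halved substeps,
        # committing each converged substep, down to 1/16 of the step
        d_cur, sub = d_prev, d - d_prev
        ok = True
        while d_cur < d - 1e-12:
            d_try = min(d_cur + sub, d)
            q0 = q if q_rate is None else q + q_rate * (d_try - d_cur)
            ok_sub, q_new, data = newton(q0, state, d_try)
            if ok_sub:
                if d_try > d_cur:
                    q_rate = (q_new - q) / (d_try - d_cur)
                q, (f_int, state, u) = q_new, data
                d_cur = d_try
            else:
                sub *= 0.5
                if sub < (d - d_prev) / 16.0 * (1 - 1e-9):
                    ok = False
                    break
        if not ok:
            converged = False
            msg = (
                f"Newton did not converge at increment {t} (d = {d:.4g} mm) even after "
                f"cutback to {sub * 2:.3g} mm substeps; returning {completed} increments"
            )
            break
        completed = t
        disp.append(d)
        reac.append(float(g @ f_int))
        peeq_hist.append(state.peeq.copy())
        rot_hist.append(q[theta_cols[0] : theta_cols[1]].copy() if theta_cols else np.zeros(3))
        if record_fields:
            fields.append(u.copy())

    disp = np.array(disp)
    reac = np.array(reac)
    curve = LoadDisplacementCurve(displacement=disp, load=reac / 1e3)
    return SolutionRecord(
        displacement=disp,
        reaction_N=reac,
        curve=curve,
        peeq_history=peeq_hist,
        rotation_history=rot_hist,
        displacement_fields=fields,
        converged=converged,
        n_increments_completed=completed,
        message=msg,
        final_state=state,
    )


def sagittal_tilt_deg(record: SolutionRecord, frame) -> np.ndarray:
    """Control-point tilt about the mediolateral axis per increment (degrees).

    Positive values tip the anterior rim caudally (the wedge direction).
    """
    ml = frame.sagittal_normal
    return np.degrees(np.array([r @ ml for r in record.rotation_history]))
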