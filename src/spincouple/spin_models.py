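"""Heisenberg(+biquadratic) spin Hamiltonians and synthetic CI fixtures.

The model is the isotropic Heisenberg-Dirac-Van Vleck Hamiltonian with an
optional biquadratic extension and a global intercept,

    H = sum_{i<j} J_ij  S_i . S_j  +  K_ij (S_i . S_j)^2  +  b,

with J > 0 antiferromagnetic and energies in cm^-1.  The module builds H
on the uncoupled product space, rotates total-spin blocks into the local
sequential or binary-tree CSF basis, produces the analytic (symbolic)
three-site S_tot = 3/2 block, and synthesizes complete "ab initio-like"
CI-vector fixtures in the standard CSF basis for the effective-
Hamiltonian pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .su2_algebra import HalfInt, HalfIntLike, clebsch_gordan
from .csf_spaces import (LocalCSF, StandardCSF, SystemSpec, TreeCSF,
                         enumerate_local, enumerate_standard, enumerate_tree,
                         hund_manifold)
from .recoupling import transform_block

__all__ = [
    "ModelParams",
    "ModelMatrix",
    "SpinOperators",
    "site_spin_operators",
    "build_model_uncoupled",
    "coupling_vectors",
    "model_in_coupled_basis",
    "analytic_three_site_block",
    "synthesize_fixture",
]

_DIM_GUARD = 100_000


@dataclass(frozen=True)
class ModelParams:
    """Couplings of the spin model: bilinear J, biquadratic K, intercept b.

    ``J`` and ``K`` are symmetric k x k matrices in cm^-1 with unused
    (zero) diagonals; ``b`` shifts every state equally.  The sign
    convention is H = +J S_i.S_j, so J > 0 is antiferromagnetic.
    """

    J: np.ndarray
    K: np.ndarray
    b: float = 0.0

    def __post_init__(self):
        J = np.asarray(self.J, dtype=float)
        K = np.asarray(self.K, dtype=float)
        for name, M in (("J", J), ("K", K)):
            if M.ndim != 2 or M.shape[0] != M.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.abs(np.diag(M)) > 0):
                raise ValueError(f"{name} diagonal must be zero")
        if J.shape != K.shape:
            raise ValueError("J and K must have the same shape")
        object.__setattr__(self, "J", J)
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "b", float(self.b))

    @staticmethod
    def from_pairs(n_sites: int, J: dict[tuple[int, int], float] | None = None,
                   K: dict[tuple[int, int], float] | None = None,
                   b: float = 0.0) -> "ModelParams":
        """Build from sparse {(i, j): value} dictionaries (0-based, i < j)."""
        Jm = np.zeros((n_sites, n_sites))
        Km = np.zeros((n_sites, n_sites))
        for target, pairs in ((Jm, J), (Km, K)):
            for (i, j), v in (pairs or {}).items():
                target[i, j] = target[j, i] = v
        return ModelParams(Jm, Km, b)

    @property
    def n_sites(self) -> int:
        return self.J.shape[0]


@dataclass(frozen=True)
class ModelMatrix:
    """Hermitian model Hamiltonian over a labelled basis (cm^-1)."""

    basis_labels: tuple[str, ...]
    matrix: np.ndarray

    @property
    def dim(self) -> int:
        return len(self.basis_labels)

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.matrix)


@dataclass(frozen=True)
class SpinOperators:
    """Angular-momentum matrices of a single spin S, dimension 2S+1.

    ``sz`` is diagonal with m = S..-S; ``sp``/``sm`` are the ladder
    operators with the standard matrix elements; ``sx``, ``sy`` derive
    from them and satisfy [sx, sy] = i sz.
    """

    spin: HalfInt
    sz: np.ndarray
    sp: np.ndarray
    sm: np.ndarray

    @property
    def sx(self) -> np.ndarray:
        return 0.5 * (self.sp + self.sm)

    @property
    def sy(self) -> np.ndarray:
        return -0.5j * (self.sp - self.sm)

    @property
    def casimir(self) -> np.ndarray:
        """S^2 = S(S+1) I."""
        return self.sx @ self.sx + np.real(self.sy @ self.sy) + self.sz @ self.sz


def site_spin_operators(spin: HalfIntLike) -> SpinOperators:
    """Standard angular-momentum matrices for one site spin."""
    s = HalfInt(spin)
    if s.twice < 1:
        raise ValueError("site spin must be >= 1/2")
    ms = np.array([float(m) for m in s.projections()])
    sval = float(s)
    sz = np.diag(ms)
    sp = np.zeros((len(ms), len(ms)))
    for i in range(1, len(ms)):
        m = ms[i]
        sp[i - 1, i] = np.sqrt(sval * (sval + 1) - m * (m + 1))
    return SpinOperators(s, sz, sp, sp.T.copy())


def _site_pair_coupling(site_spins: Sequence[HalfInt], i: int,
                        j: int) -> np.ndarray:
    """S_i . S_j on the full product space (real symmetric)."""
    ops = [site_spin_operators(s) for s in site_spins]
    dims = [s.multiplicity for s in site_spins]

    def embed(mats: dict[int, np.ndarray]) -> np.ndarray:
        out = np.ones((1, 1))
        for idx, d in enumerate(dims):
            out = np.kron(out, mats.get(idx, np.eye(d)))
        return out

    dot = embed({i: ops[i].sz, j: ops[j].sz})
    dot += 0.5 * embed({i: ops[i].sp, j: ops[j].sm})
    dot += 0.5 * embed({i: ops[i].sm, j: ops[j].sp})
    return dot


def _uncoupled_labels(site_spins: Sequence[HalfInt]) -> tuple[str, ...]:
    import itertools
    grids = [s.projections() for s in site_spins]
    return tuple("|" + ",".join(str(m) for m in combo) + ">"
                 for combo in itertools.product(*grids))


def build_model_uncoupled(site_spins: Sequence[HalfIntLike],
                          params: ModelParams) -> ModelMatrix:
    """H on the full product basis (dimension prod(2S_i + 1)).

    Commutes with S_tot,z and S_tot^2; the coupled-basis blocks of
    :func:`model_in_coupled_basis` are its exact spin blocks.
    """
    spins = [HalfInt(s) for s in site_spins]
    if len(spins) < 2:
        raise ValueError("need at least two sites")
    if len(spins) != params.n_sites:
        raise ValueError("params dimension does not match site count")
    dim = int(np.prod([s.multiplicity for s in spins]))
    if dim > _DIM_GUARD:
        raise ValueError(f"product space dimension {dim} exceeds guard "
                         f"{_DIM_GUARD}")
    H = params.b * np.eye(dim)
    for i in range(len(spins)):
        for j in range(i + 1, len(spins)):
            if params.J[i, j] == 0.0 and params.K[i, j] == 0.0:
                continue
            dot = _site_pair_coupling(spins, i, j)
            H += params.J[i, j] * dot + params.K[i, j] * (dot @ dot)
    return ModelMatrix(_uncoupled_labels(spins), H)


# ---------------------------------------------------------------------------
# coupled bases over site spins


def coupling_vectors(csfs: Sequence[Union[LocalCSF, TreeCSF]]) -> np.ndarray:
    """Columns = coupled CSFs expanded over site projections at M = S_tot.

    Works at the site-spin level (sites are rigid spins); the CSFs must
    share site spins and total spin.  Used to rotate product-space
    operators into a coupled block.
    """
    import itertools
    first = csfs[0]
    spins = first.site_spins
    total = first.total_spin
    grids = [s.projections() for s in spins]
    basis_m = list(itertools.product(*grids))
    index = {tuple(m.twice for m in combo): r
             for r, combo in enumerate(basis_m)}
    dim = len(basis_m)
    out = np.zeros((dim, len(csfs)))

    def chain_amp(path, units_twice, ms_twice) -> float:
        amp, acc = 1.0, ms_twice[0]
        for j in range(1, len(ms_twice)):
            if abs(acc) > path[j - 1].twice or \
                    abs(acc + ms_twice[j]) > path[j].twice:
                return 0.0  # projection outside the multiplet
            amp *= float(clebsch_gordan(
                HalfInt(twice=path[j - 1].twice), HalfInt(twice=acc),
                HalfInt(twice=units_twice[j]), HalfInt(twice=ms_twice[j]),
                HalfInt(twice=path[j].twice), HalfInt(twice=acc + ms_twice[j])))
            if amp == 0.0:
                return 0.0
            acc += ms_twice[j]
        return amp

    units = [s.twice for s in spins]
    for col, csf in enumerate(csfs):
        if csf.site_spins != spins or csf.total_spin != total:
            raise ValueError("CSFs must share site spins and total spin")
        for combo in basis_m:
            ms = [m.twice for m in combo]
            if sum(ms) != total.twice:
                continue
            if isinstance(csf, LocalCSF):
                amp = chain_amp(csf.couplings, units, ms)
            else:
                # ((AB)(CD)): pair amplitudes, then pair-spin coupling
                amp = 0.0
                mab = ms[0] + ms[1]
                mcd = ms[2] + ms[3]
                if abs(mab) <= csf.s_ab.twice and abs(mcd) <= csf.s_cd.twice:
                    a1 = float(clebsch_gordan(
                        spins[0], HalfInt(twice=ms[0]), spins[1],
                        HalfInt(twice=ms[1]), csf.s_ab, HalfInt(twice=mab)))
                    a2 = float(clebsch_gordan(
                        spins[2], HalfInt(twice=ms[2]), spins[3],
                        HalfInt(twice=ms[3]), csf.s_cd, HalfInt(twice=mcd)))
                    a3 = float(clebsch_gordan(
                        csf.s_ab, HalfInt(twice=mab), csf.s_cd,
                        HalfInt(twice=mcd), total, HalfInt(twice=total.twice)))
                    amp = a1 * a2 * a3
            if amp != 0.0:
                out[index[tuple(ms)], col] = amp
    return out


def model_in_coupled_basis(site_spins: Sequence[HalfIntLike],
                           params: ModelParams, scheme: str,
                           total_spin: HalfIntLike) -> ModelMatrix:
    """The S_tot block of the model in the local or tree coupling scheme.

    Conjugates the uncoupled-basis Hamiltonian with the Clebsch-Gordan
    coupling tree of the requested scheme; because H is isotropic the
    block is exact (no leakage to other total spins).
    """
    spins = tuple(HalfInt(s) for s in site_spins)
    spec = SystemSpec.from_site_spins(spins, total_spin)
    if scheme == "local":
        basis = enumerate_local(spec)
    elif scheme == "tree":
        basis = enumerate_tree(spec)
    else:
        raise ValueError("scheme must be 'local' or 'tree'")
    if not basis:
        return ModelMatrix((), np.zeros((0, 0)))
    V = coupling_vectors(basis)
    H = build_model_uncoupled(spins, params).matrix
    block = V.T @ H @ V
    block = 0.5 * (block + block.T)
    return ModelMatrix(tuple(b.label for b in basis), block)


# ---------------------------------------------------------------------------
# analytic three-site block (three S = 3/2 sites, S_tot = 3/2)


@lru_cache(maxsize=1)
def _three_site_coefficient_matrices():
    """Exact sympy 4x4 blocks: coefficient of each J_ij/K_ij on the
    S_tot = 3/2 coupled basis |S_tot; S_12> of three S = 3/2 sites.

    Assembled with sympy's own Clebsch-Gordan coefficients and exact
    rational spin matrices — an arithmetic path independent of the float
    construction it arbitrates.
    """
    import itertools
    import sympy
    from sympy import Rational, sqrt, S as Sym
    from sympy.physics.wigner import clebsch_gordan as sym_cg

    s = Rational(3, 2)
    ms = [s - i for i in range(4)]
    dim = 4

    sz = sympy.diag(*ms)
    sp = sympy.zeros(dim)
    for i in range(1, dim):
        m = ms[i]
        sp[i - 1, i] = sqrt(s * (s + 1) - m * (m + 1))
    sm = sp.T

    def pair_dot(i, j):
        def kron3(a, b, c):
            return sympy.Matrix(sympy.kronecker_product(a, b, c))
        zz = kron3(*[(sz if idx in (i, j) else sympy.eye(dim))
                     for idx in range(3)])
        pmm = [sp if idx == i else (sm if idx == j else sympy.eye(dim))
               for idx in range(3)]
        mmp = [sm if idx == i else (sp if idx == j else sympy.eye(dim))
               for idx in range(3)]
        return zz + Rational(1, 2) * (kron3(*pmm) + kron3(*mmp))

    # coupled basis |(S12) S_tot=3/2, M=3/2>
    total = Rational(3, 2)
    combos = list(itertools.product(ms, repeat=3))
    V = sympy.zeros(dim ** 3, 4)
    for col, s12 in enumerate((0, 1, 2, 3)):
        for row, (m1, m2, m3) in enumerate(combos):
            if m1 + m2 + m3 != total:
                continue
            m12 = m1 + m2
            if abs(m12) > s12:
                continue
            amp = sym_cg(s, s, Sym(s12), m1, m2, m12) * \
                sym_cg(Sym(s12), s, total, m12, m3, total)
            V[row, col] = amp
    coeffs = {}
    for (i, j) in ((0, 1), (0, 2), (1, 2)):
        dot = pair_dot(i, j)
        coeffs[("J", i, j)] = sympy.simplify(V.T * dot * V)
        coeffs[("K", i, j)] = sympy.simplify(V.T * dot * dot * V)
    return coeffs


def analytic_three_site_block(params: Optional[ModelParams] = None):
    """Analytic S_tot = 3/2 block for three S = 3/2 sites.

    With ``params=None`` returns a symbolic sympy 4x4 matrix over the
    basis |3/2; S_12 = 0..3> in the symbols J12, J13, J23, K12, K13,
    K23, b.  With explicit parameters returns the numeric ndarray.  The
    block is diagonal when J13 = J23 and K = 0, and the (S_12=0, S_12=3)
    corner vanishes identically for all parameters.
    """
    import sympy
    coeffs = _three_site_coefficient_matrices()
    syms = {name: sympy.Symbol(name) for name in
            ("J12", "J13", "J23", "K12", "K13", "K23", "b")}
    expr = syms["b"] * sympy.eye(4)
    names = {(0, 1): "12", (0, 2): "13", (1, 2): "23"}
    for (i, j), tag in names.items():
        expr = expr + syms["J" + tag] * coeffs[("J", i, j)] \
            + syms["K" + tag] * coeffs[("K", i, j)]
    if params is None:
        return sympy.simplify(expr)
    subs = {syms["b"]: params.b}
    for (i, j), tag in names.items():
        subs[syms["J" + tag]] = params.J[i, j]
        subs[syms["K" + tag]] = params.K[i, j]
    return np.array(expr.subs(subs).evalf(), dtype=float)


# ---------------------------------------------------------------------------
# synthetic fixtures


def synthesize_fixture(spec: SystemSpec, params: ModelParams,
                       non_hund_gap: float = 1.0e4, mixing: float = 1.0e2,
                       seed: int = 0,
                       ) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Synthetic CI vectors and energies in the standard CSF basis.

    Emulates what a CI calculation hands the extraction pipeline: the
    spin model acts on the Hund manifold (every site at maximal spin),
    non-Hund local CSFs sit a gap ``non_hund_gap`` (cm^-1) higher, and a
    seeded random symmetric coupling of magnitude ``mixing`` (cm^-1)
    admixes them (Hund <-> non-Hund and within non-Hund).  The full
    Hamiltonian is diagonalized and the model-dimension roots with the
    largest Hund-manifold weight are returned, expressed in the standard
    genealogical basis.

    Returns ``(energies, civec, retained_norm)`` where ``civec`` is a
    DataFrame with columns (state, csf_label, coefficient) and
    ``retained_norm[i]`` the Hund weight of root i.  With ``mixing=0``
    the model eigenpairs are recovered exactly; output is a
    deterministic function of the seed.
    """
    if non_hund_gap <= 0:
        raise ValueError("non_hund_gap must be positive")
    if not spec.electron_resolved:
        raise ValueError("fixtures need an electron-resolved system")
    local = enumerate_local(spec)
    hund_idx = [i for i, l in enumerate(local) if l.is_hund]
    other_idx = [i for i, l in enumerate(local) if not l.is_hund]
    if not hund_idx:
        raise ValueError("empty Hund manifold for this block")
    d = len(local)
    dm = len(hund_idx)

    model = model_in_coupled_basis(spec.max_site_spins, params, "local",
                                   spec.total_spin)
    # model basis is spin-only labelled; align with the electron-resolved
    # Hund labels via the coupling chains
    chain_of = {tuple(s.twice for s in LocalCSF.parse(lbl).couplings): r
                for r, lbl in enumerate(model.basis_labels)}
    perm = [chain_of[tuple(s.twice for s in local[i].couplings)]
            for i in hund_idx]
    Hm = model.matrix[np.ix_(perm, perm)]

    H = np.zeros((d, d))
    H[np.ix_(hund_idx, hund_idx)] = Hm
    H[other_idx, other_idx] = non_hund_gap
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((d, d))
    noise = (noise + noise.T) / np.sqrt(2.0)
    mask = np.ones((d, d), dtype=bool)
    mask[np.ix_(hund_idx, hund_idx)] = False  # model block stays exact
    # "mixing" is the total coupling strength per root: with matrix
    # elements ~ N(0, t^2/d_bath) each model root couples to the bath
    # with summed squared strength t^2, so the discarded norm per root is
    # O(t^2/gap^2) independent of the bath dimension.
    scale = mixing / np.sqrt(max(len(other_idx), 1))
    H = H + scale * noise * mask

    evals, evecs = np.linalg.eigh(H)
    weights = np.sum(evecs[hund_idx, :] ** 2, axis=0)
    roots = np.sort(np.argsort(-weights)[:dm])
    energies = evals[roots]
    vec_local = evecs[:, roots]
    retained = weights[roots]

    std = enumerate_standard(spec.n_electrons, spec.total_spin)
    T = transform_block(spec, std, local)  # <C|L>
    vec_std = T.matrix @ vec_local

    records = []
    for r in range(dm):
        for i, csf in enumerate(std):
            coef = vec_std[i, r]
            if coef != 0.0:
                records.append((r, csf.label, coef))
    civec = pd.DataFrame(records, columns=["state", "csf_label", "coefficient"])
    return energies, civec, retained
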