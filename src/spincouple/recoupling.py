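"""Recoupling transformations between spin-coupling schemes.

The central object is the overlap ``<C|L>`` between a genealogical CSF
(electrons coupled one at a time) and a local sequential CSF (electrons
pre-coupled within each site, site spins then chained).  Because both
schemes couple the same leading subsets of electrons, the overlap
carries Kronecker deltas — the intra-site path of site 1 must coincide
with the head of the genealogical path, and the cumulative spin at every
site boundary must equal the corresponding running coupling — and the
rest is a closed product of dimension-weighted Racah symbols, one per
electron beyond the first on every site beyond the first:

    <C|L> = delta(site-1 path) * prod_i delta(boundary_i)
            * prod_{i>=2} prod_{m=2}^{n_i}
              W~(T_{i-1}, V_{m-1}, U_m, 1/2; U_{m-1}, V_m)

where T_{i-1} is the running coupling before site i, V_m the intra-site
cumulative spins of site i and U_m the genealogical cumulative spins
over site i's electrons.  The identity behind each factor is the
elementary recoupling bracket

    <(j1 j2) J12, j3; J | j1, (j2 j3) J23; J> = W~(j1, j2, J, j3; J12, J23),

applied once per electron; nothing in the derivation requires the sites
to carry equal electron counts.  A brute-force Clebsch-Gordan
contraction over all uncoupled product states (:func:`oracle_recouple`)
provides a convention-independent check and is the arbiter used by the
test suite.

The (((AB)C)D) -> ((AB)(CD)) binary-tree transform is a single weighted
Racah symbol (:func:`tree_recouple`); full basis-change matrices for a
block are assembled by :func:`transform_matrix`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence, Union

import numpy as np

from .su2_algebra import (HALF, HalfInt, SymbolValue, clebsch_gordan,
                          triangle_ok, weighted_w)
from .csf_spaces import (CSF, LocalCSF, StandardCSF, SystemSpec, TreeCSF,
                         enumerate_local, enumerate_standard, enumerate_tree)

__all__ = [
    "TransformMatrix",
    "UgaDVector",
    "recouple_closed",
    "oracle_recouple",
    "tree_recouple",
    "transform_matrix",
    "transform_block",
    "guga_phase",
    "d_vector_to_standard",
]

SCHEMES = ("standard", "local", "tree")


def _require_block_match(spec: SystemSpec, c: StandardCSF, l: LocalCSF) -> None:
    if c.n_electrons != spec.n_electrons:
        raise ValueError(f"standard CSF has {c.n_electrons} electrons, "
                         f"system has {spec.n_electrons}")
    if c.total_spin != spec.total_spin or l.total_spin != spec.total_spin:
        raise ValueError("CSFs belong to different total-spin blocks")
    if l.intra_paths is None:
        raise ValueError("local CSF must be electron-resolved "
                         "(carry intra-site paths) for <C|L>")
    if tuple(len(p) for p in l.intra_paths) != spec.electrons_per_site:
        raise ValueError("local CSF site sizes do not match the system")


def recouple_closed(spec: SystemSpec, c: StandardCSF, l: LocalCSF) -> SymbolValue:
    """Closed-form recoupling coefficient <C|L>, exact.

    Structural zeros (violated deltas or Racah triangles) return exact
    zero.  The coefficient is a product of (n_i - 1) weighted Racah
    symbols per site beyond the first — for an equal chain of k sites of
    n electrons, (k-1)(n-1) symbols in total.
    """
    _require_block_match(spec, c, l)
    boundaries = spec.site_boundaries()
    # delta: intra-site path of site 1 equals the head of the standard path
    n1 = boundaries[0]
    if c.cumulative[:n1] != l.intra_paths[0]:
        return SymbolValue.zero()
    # deltas: cumulative spin at every site boundary equals the running coupling
    for i, edge in enumerate(boundaries):
        if c.cumulative[edge - 1] != l.couplings[i]:
            return SymbolValue.zero()
    value = SymbolValue.one()
    for i in range(1, spec.n_sites):
        t_prev = l.couplings[i - 1]
        v = l.intra_paths[i]
        offset = boundaries[i - 1]  # electrons before site i+1 (0-based site i)
        u = c.cumulative[offset:boundaries[i]]
        for m in range(1, len(v)):
            value = value * weighted_w(t_prev, v[m - 1], u[m], HALF,
                                       u[m - 1], v[m])
            if value.is_zero:
                return value
    return value


# ---------------------------------------------------------------------------
# Clebsch-Gordan contraction oracle (resolution of the identity over all
# uncoupled product states)


@lru_cache(maxsize=None)
def _cg_float(tj1: int, tm1: int, tj2: int, tm2: int, tJ: int, tM: int) -> float:
    if abs(tm1) > tj1 or abs(tm2) > tj2 or abs(tM) > tJ:
        return 0.0  # projection outside the multiplet: zero amplitude
    return float(clebsch_gordan(HalfInt(twice=tj1), HalfInt(twice=tm1),
                                HalfInt(twice=tj2), HalfInt(twice=tm2),
                                HalfInt(twice=tJ), HalfInt(twice=tM)))


def _chain_amplitude_units(path: Sequence[HalfInt], unit_spins: Sequence[int],
                           ms: Sequence[int]) -> float:
    """<m-string | sequential coupling chain>, float.

    ``unit_spins``/``ms`` are doubled spins and projections of the units
    being chained; ``path`` the cumulative spins (path[0] == unit 0).
    """
    amp = 1.0
    acc = ms[0]
    for j in range(1, len(ms)):
        amp *= _cg_float(path[j - 1].twice, acc, unit_spins[j], ms[j],
                         path[j].twice, acc + ms[j])
        if amp == 0.0:
            return 0.0
        acc += ms[j]
    return amp


def _standard_amplitude(c: StandardCSF, ms: Sequence[int]) -> float:
    return _chain_amplitude_units(c.cumulative, [1] * len(ms), ms)


def _local_amplitude(l: LocalCSF, sizes: Sequence[int], ms: Sequence[int]) -> float:
    """<electron m-string | local CSF>, float, via intra- then inter-site CG."""
    amp = 1.0
    site_m = []
    pos = 0
    for path, n in zip(l.intra_paths, sizes):
        site_ms = ms[pos:pos + n]
        amp *= _chain_amplitude_units(path, [1] * n, site_ms)
        if amp == 0.0:
            return 0.0
        site_m.append(sum(site_ms))
        pos += n
    amp *= _chain_amplitude_units(l.couplings,
                                  [s.twice for s in l.site_spins], site_m)
    return amp


def _m_strings(n: int, total: int):
    """All doubled +-1 strings of length n with fixed doubled sum."""
    n_up = (total + n) // 2
    for ups in itertools.combinations(range(n), n_up):
        ms = [-1] * n
        for i in ups:
            ms[i] = 1
        yield ms


def oracle_recouple(spec: SystemSpec, c: StandardCSF, l: LocalCSF) -> float:
    """<C|L> by brute-force CG contraction over all uncoupled states.

    Independent of any Racah/6j code path; cost 2^N per pair, intended
    for N up to ~12 at test scale.  Evaluated in the stretched
    projection block M = S_tot.
    """
    _require_block_match(spec, c, l)
    n = spec.n_electrons
    sizes = spec.electrons_per_site
    total = spec.total_spin.twice
    acc = 0.0
    for ms in _m_strings(n, total):
        a = _standard_amplitude(c, ms)
        if a == 0.0:
            continue
        acc += a * _local_amplitude(l, sizes, ms)
    return acc


def tree_recouple(l: LocalCSF, t: TreeCSF) -> SymbolValue:
    """Recoupling coefficient <L|T> for four sites, exact.

    The (((AB)C)D) -> ((AB)(CD)) transformation: S_AB is shared by both
    schemes (Kronecker delta against the first running coupling T_2) and
    the remaining rearrangement is the single weighted Racah symbol
    W~(S_AB, S_C, S_tot, S_D; T_3, S_CD).
    """
    if l.n_sites != 4:
        raise ValueError("tree recoupling requires four sites")
    if l.total_spin != t.total_spin:
        raise ValueError("CSFs belong to different total-spin blocks")
    if (l.intra_paths is None) != (t.intra_paths is None):
        raise ValueError("mixed electron-resolved and spin-only CSFs")
    if l.site_spins != t.site_spins:
        return SymbolValue.zero()  # different site-spin sectors: delta
    if l.intra_paths is not None and l.intra_paths != t.intra_paths:
        return SymbolValue.zero()
    if l.couplings[1] != t.s_ab:
        return SymbolValue.zero()
    sc, sd = l.site_spins[2], l.site_spins[3]
    return weighted_w(t.s_ab, sc, l.total_spin, sd, l.couplings[2], t.s_cd)


# ---------------------------------------------------------------------------
# full transformation matrices


@dataclass(frozen=True)
class TransformMatrix:
    """Orthogonal basis-change matrix T[i, j] = <row_i | col_j>.

    A coefficient vector given over the row basis transforms to the
    column basis as ``c_col = T.T @ c_row``.  ``exact`` holds the
    SymbolValue entries when the matrix was assembled in closed form
    (None for composed float-only paths).
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    matrix: np.ndarray
    exact: Optional[tuple[tuple[SymbolValue, ...], ...]] = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def apply(self, coeffs: np.ndarray) -> np.ndarray:
        """Transform row-basis coefficients to the column basis."""
        return self.matrix.T @ coeffs

    def transpose(self) -> "TransformMatrix":
        exact = None
        if self.exact is not None:
            exact = tuple(zip(*self.exact))
        return TransformMatrix(self.col_labels, self.row_labels,
                               self.matrix.T.copy(), exact)

    def nonzero_rows(self, cols: Optional[Sequence[int]] = None,
                     tol: float = 0.0) -> int:
        """Rows with at least one (structurally) nonzero entry.

        With exact entries available, ``tol`` is ignored and structural
        zeros are decided in exact arithmetic.
        """
        if self.exact is not None:
            idx = range(len(self.col_labels)) if cols is None else cols
            return sum(1 for row in self.exact
                       if any(not row[j].is_zero for j in idx))
        sub = self.matrix if cols is None else self.matrix[:, list(cols)]
        return int(np.sum(np.any(np.abs(sub) > max(tol, 1e-10), axis=1)))


def _basis_for(spec: SystemSpec, scheme: str) -> list[CSF]:
    if scheme == "standard":
        return enumerate_standard(spec.n_electrons, spec.total_spin)
    if scheme == "local":
        return enumerate_local(spec)
    if scheme == "tree":
        return enumerate_tree(spec)
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


@lru_cache(maxsize=64)
def _transform_cached(spec: SystemSpec, scheme_from: str,
                      scheme_to: str) -> TransformMatrix:
    rows = _basis_for(spec, scheme_from)
    cols = _basis_for(spec, scheme_to)
    pair = (scheme_from, scheme_to)
    if pair in {("standard", "local"), ("local", "standard")}:
        flip = pair[0] == "local"
        std, loc = (cols, rows) if flip else (rows, cols)
        exact = [[recouple_closed(spec, c, l) for l in loc] for c in std]
        if flip:
            exact = [list(col) for col in zip(*exact)]
    elif pair in {("local", "tree"), ("tree", "local")}:
        flip = pair[0] == "tree"
        loc, tre = (cols, rows) if flip else (rows, cols)
        exact = [[tree_recouple(l, t) for t in tre] for l in loc]
        if flip:
            exact = [list(col) for col in zip(*exact)]
    else:
        # standard <-> tree by composition through the local scheme (float)
        first = _transform_cached(spec, scheme_from, "local")
        second = _transform_cached(spec, "local", scheme_to)
        mat = first.matrix @ second.matrix
        return TransformMatrix(tuple(b.label for b in rows),
                               tuple(b.label for b in cols), mat, None)
    mat = np.array([[float(v) for v in row] for row in exact])
    return TransformMatrix(tuple(b.label for b in rows),
                           tuple(b.label for b in cols), mat,
                           tuple(tuple(row) for row in exact))


def transform_block(spec: SystemSpec, rows: Sequence[CSF],
                    cols: Sequence[CSF]) -> TransformMatrix:
    """Exact transformation block between explicit CSF lists.

    Rows and columns may be standard/local (closed form) or local/tree
    CSFs; useful for restricted blocks such as the Hund manifold, where
    the full square matrix is not needed.
    """
    def entry(a: CSF, b: CSF) -> SymbolValue:
        if isinstance(a, StandardCSF) and isinstance(b, LocalCSF):
            return recouple_closed(spec, a, b)
        if isinstance(a, LocalCSF) and isinstance(b, StandardCSF):
            return recouple_closed(spec, b, a)
        if isinstance(a, LocalCSF) and isinstance(b, TreeCSF):
            return tree_recouple(a, b)
        if isinstance(a, TreeCSF) and isinstance(b, LocalCSF):
            return tree_recouple(b, a)
        raise ValueError(f"unsupported scheme pair "
                         f"({type(a).__name__}, {type(b).__name__})")

    exact = tuple(tuple(entry(a, b) for b in cols) for a in rows)
    mat = np.array([[float(v) for v in row] for row in exact])
    return TransformMatrix(tuple(a.label for a in rows),
                           tuple(b.label for b in cols), mat, exact)


def transform_matrix(spec: SystemSpec, scheme_from: str,
                     scheme_to: str) -> TransformMatrix:
    """Full orthogonal basis-change matrix for one (N, S_tot) block.

    ``standard <-> local`` and ``local <-> tree`` are assembled from the
    closed forms in exact arithmetic; ``standard <-> tree`` is their
    composition.  The tree scheme requires four sites.  Results are
    memoized per (system, scheme pair).
    """
    if scheme_from == scheme_to:
        basis = _basis_for(spec, scheme_from)
        labels = tuple(b.label for b in basis)
        eye = tuple(tuple(SymbolValue.one() if i == j else SymbolValue.zero()
                          for j in range(len(basis))) for i in range(len(basis)))
        return TransformMatrix(labels, labels, np.eye(len(basis)), eye)
    if "standard" in (scheme_from, scheme_to) and not spec.electron_resolved:
        raise ValueError("standard scheme requires an electron-resolved system")
    return _transform_cached(spec, scheme_from, scheme_to)


# ---------------------------------------------------------------------------
# UGA step-vector phase adapter


@dataclass(frozen=True)
class UgaDVector:
    """Unitary-group-approach step vector; values in {0, 1, 2, 3}.

    Step values per orbital: 0 empty, 1 spin-raising single occupation,
    2 spin-lowering single occupation, 3 double occupation.  The
    cumulative intermediate spin (b value) must stay non-negative.
    """

    levels: tuple[int, ...]

    def __post_init__(self):
        levels = tuple(int(d) for d in self.levels)
        object.__setattr__(self, "levels", levels)
        if any(d not in (0, 1, 2, 3) for d in levels):
            raise ValueError("step values must be in {0, 1, 2, 3}")
        if any(b < 0 for b in self.b_values):
            raise ValueError("step vector dips below spin zero")

    @property
    def b_values(self) -> tuple[int, ...]:
        """Doubled cumulative spin after each level."""
        out, b = [], 0
        for d in self.levels:
            b += (d == 1) - (d == 2)
            out.append(b)
        return tuple(out)

    @staticmethod
    def parse(text: str) -> "UgaDVector":
        return UgaDVector(tuple(int(ch) for ch in text.strip()))

    def __str__(self) -> str:
        return "".join(str(d) for d in self.levels)


def guga_phase(d: UgaDVector) -> int:
    """Sign converting a UGA-convention CI coefficient to genealogical.

    The two conventions differ only on levels with step value 2 or 3
    (negative coupling or double occupation); each such level l
    contributes (-1)^(b_l) with b_l twice the cumulative spin after the
    level.  A step vector without such levels (e.g. any high-spin
    stretched CSF) gets phase +1, and applying the phase twice is the
    identity.
    """
    if isinstance(d, str):
        d = UgaDVector.parse(d)
    exponent = sum(b for level, b in zip(d.levels, d.b_values)
                   if level in (2, 3))
    return -1 if exponent % 2 else 1


def d_vector_to_standard(d: UgaDVector) -> StandardCSF:
    """Genealogical CSF of an all-singly-occupied step vector."""
    if isinstance(d, str):
        d = UgaDVector.parse(d)
    if any(level in (0, 3) for level in d.levels):
        raise ValueError("only singly occupied step vectors map to a "
                         "genealogical path")
    return StandardCSF(tuple(HalfInt(twice=b) for b in d.b_values))
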