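"""Effective-Hamiltonian construction and coupling-constant extraction.

Implements the des Cloizeaux-style effective Hamiltonian on a spin-model
space: eigenvectors of the full problem, expressed in a basis compatible
with the model, are (i) projected onto the model space (tracking the
discarded norm), (ii) Löwdin-orthonormalized (the symmetric S^(-1/2)
choice keeps the projections maximally similar to the inputs and makes
the result Hermitian) and (iii) combined with the input energies through
the inverted spectral decomposition

    H_eff = sum_i |psi~_i> E_i <psi~_i| .

By construction the eigenvalues of H_eff equal the input energies.
Magnetic couplings then follow from a linear least-squares fit of the
numerical H_eff blocks to the analytic matrix of the Heisenberg
(+biquadratic) model; the fit is joint over all supplied total-spin
blocks with equal element weights and one global intercept.

Sparsity diagnostics (L1 norm and inverse participation ratio of CI
vectors) complete the toolbox.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .su2_algebra import HalfInt
from .csf_spaces import LocalCSF, TreeCSF, parse_label
from .spin_models import ModelParams, model_in_coupled_basis
from .recoupling import transform_matrix
from .csf_spaces import SystemSpec, enumerate_standard

logger = logging.getLogger(__name__)

__all__ = [
    "EffHamResult",
    "FitResult",
    "civec_matrix",
    "project_and_orthonormalize",
    "build_heff",
    "extract_effective_hamiltonian",
    "fit_params",
    "sparsity_measures",
]

LOW_NORM_WARNING = 0.9  # retained-norm fraction below which we flag a root


@dataclass(frozen=True)
class EffHamResult:
    """Numerical effective Hamiltonian on a model basis (cm^-1)."""

    basis_labels: tuple[str, ...]
    matrix: np.ndarray
    energies: np.ndarray
    retained_norm: np.ndarray

    @property
    def dim(self) -> int:
        return len(self.basis_labels)


@dataclass(frozen=True)
class FitResult:
    """Least-squares estimate of the model parameters.

    ``r_squared`` is the coefficient of determination over all stacked
    independent matrix elements; ``residuals`` maps each block index to
    its residual matrix (numerical minus fitted analytic).
    """

    params: ModelParams
    r_squared: float
    residuals: tuple[np.ndarray, ...]
    free_names: tuple[str, ...]


def civec_matrix(civec: pd.DataFrame,
                 basis_labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Pivot a (state, csf_label, coefficient) table onto a label basis.

    Returns ``(C, total_norm)`` where column i of ``C`` holds root i's
    coefficients on ``basis_labels`` and ``total_norm[i]`` is the squared
    norm of the full root vector (labels outside the basis included), so
    the caller can account for discarded components.
    """
    states = sorted(civec["state"].unique())
    index = {lbl: r for r, lbl in enumerate(basis_labels)}
    C = np.zeros((len(basis_labels), len(states)))
    total = np.zeros(len(states))
    for col, state in enumerate(states):
        sub = civec[civec["state"] == state]
        if sub["csf_label"].duplicated().any():
            dup = sub[sub["csf_label"].duplicated()]["csf_label"].iloc[0]
            raise ValueError(f"duplicate (state, label) entry: ({state}, {dup})")
        for lbl, coef in zip(sub["csf_label"], sub["coefficient"]):
            total[col] += coef * coef
            r = index.get(lbl)
            if r is not None:
                C[r, col] = coef
    return C, total


def project_and_orthonormalize(
        projections: np.ndarray,
        total_norms: Optional[np.ndarray] = None,
        rank_tol: float = 1.0e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Löwdin symmetric orthonormalization of model-space projections.

    ``projections`` holds one root per column, already expressed on the
    model basis; ``total_norms`` the squared norms of the full input
    vectors (defaults to 1, i.e. inputs assumed normalized).  Returns
    ``(U, retained)`` with ``U = P (P^T P)^(-1/2)`` orthonormal and
    ``retained[i] = ||P_i||^2 / total_norm_i``.

    Raises ``ValueError`` naming the offending roots when the projected
    vectors do not span the model space (singular overlap).
    """
    P = np.asarray(projections, dtype=float)
    d, n = P.shape
    if n != d:
        raise ValueError(f"need as many roots as model dimensions ({n} vs {d})")
    if total_norms is None:
        total_norms = np.ones(n)
    retained = np.sum(P * P, axis=0) / np.asarray(total_norms, dtype=float)
    S = P.T @ P
    evals, evecs = np.linalg.eigh(S)
    if evals[0] < rank_tol * max(evals[-1], 1.0):
        bad = [i for i in range(n)
               if abs(evecs[i, 0]) > 1.0 / np.sqrt(2 * n)]
        raise ValueError(
            "singular overlap: projections are (numerically) rank deficient; "
            f"roots involved in the null direction: {bad}")
    inv_sqrt = evecs @ np.diag(evals ** -0.5) @ evecs.T
    U = P @ inv_sqrt
    low = np.nonzero(retained < LOW_NORM_WARNING)[0]
    if low.size:
        logger.warning("low retained norm after model-space projection: %s",
                       ", ".join(f"root {i}: {retained[i]:.3f}" for i in low))
    return U, retained


def build_heff(orthonormal: np.ndarray, energies: np.ndarray,
               basis_labels: Sequence[str],
               retained_norm: Optional[np.ndarray] = None,
               orthonormal_tol: float = 1.0e-8) -> EffHamResult:
    """Invert the spectral decomposition with the supplied energies.

    ``H_eff = U diag(E) U^T`` for orthonormal ``U``; Hermitian by
    construction with eigenvalues exactly ``energies``.  Raises if ``U``
    is not orthonormal to ``orthonormal_tol``.
    """
    U = np.asarray(orthonormal, dtype=float)
    E = np.asarray(energies, dtype=float)
    gram_dev = np.max(np.abs(U.T @ U - np.eye(U.shape[1])))
    if gram_dev > orthonormal_tol:
        raise ValueError(f"projections are not orthonormal "
                         f"(Gram deviation {gram_dev:.2e})")
    H = U @ np.diag(E) @ U.T
    H = 0.5 * (H + H.T)
    if retained_norm is None:
        retained_norm = np.ones(len(E))
    return EffHamResult(tuple(basis_labels), H, E.copy(),
                        np.asarray(retained_norm, dtype=float))


def extract_effective_hamiltonian(civec: pd.DataFrame, energies: np.ndarray,
                                  spec: SystemSpec, scheme: str = "local",
                                  ) -> EffHamResult:
    """Full pipeline: standard-basis CI vectors to H_eff on the model space.

    Steps: recouple the standard-scheme coefficients into the requested
    scheme, project onto the Hund manifold (all site spins maximal),
    Löwdin-orthonormalize, and invert the spectral decomposition with
    the input energies.  The model basis is labelled with spin-only
    local/tree labels matching :func:`model_in_coupled_basis`.
    """
    std = enumerate_standard(spec.n_electrons, spec.total_spin)
    std_labels = [c.label for c in std]
    C_std, total = civec_matrix(civec, std_labels)
    T = transform_matrix(spec, "standard", scheme)
    C_scheme = T.apply(C_std)

    # model space: the Hund (maximal site spin) labels of the scheme basis
    model_spec = SystemSpec.from_site_spins(spec.max_site_spins,
                                            spec.total_spin)
    model = model_in_coupled_basis(spec.max_site_spins,
                                   ModelParams.from_pairs(spec.n_sites),
                                   scheme, spec.total_spin)
    # align electron-resolved Hund labels with the spin-only model labels
    rows = []
    for lbl in model.basis_labels:
        spin_only = parse_label(lbl)
        for r, full in enumerate(T.col_labels):
            cand = parse_label(full)
            if isinstance(cand, LocalCSF) and isinstance(spin_only, LocalCSF):
                if cand.is_hund and cand.couplings == spin_only.couplings:
                    rows.append(r)
                    break
            elif isinstance(cand, TreeCSF) and isinstance(spin_only, TreeCSF):
                if (cand.intra_paths is None or
                        all(s.twice == len(p) for s, p in
                            zip(cand.site_spins, cand.intra_paths))) and \
                        (cand.s_ab, cand.s_cd) == (spin_only.s_ab,
                                                   spin_only.s_cd):
                    rows.append(r)
                    break
        else:
            raise RuntimeError(f"model label {lbl} not found in scheme basis")
    P = C_scheme[rows, :]
    U, retained = project_and_orthonormalize(P, total)
    return build_heff(U, energies, model.basis_labels, retained)


_PARAM_TAGS = ("J", "K")


def _free_param_list(n_sites: int, free: Optional[Sequence[str]]) -> list[str]:
    all_names = [f"{tag}{i + 1}{j + 1}" for tag in _PARAM_TAGS
                 for i in range(n_sites) for j in range(i + 1, n_sites)]
    if free is None:
        return all_names
    unknown = set(free) - set(all_names)
    if unknown:
        raise ValueError(f"unknown parameter names: {sorted(unknown)}")
    return [n for n in all_names if n in set(free)]


def fit_params(blocks: Sequence[EffHamResult],
               site_spins: Sequence, free: Optional[Sequence[str]] = None,
               ) -> FitResult:
    """Joint linear least-squares fit of H_eff blocks to the spin model.

    ``free`` lists the free coupling names ("J12", "K13", ...); omitted
    couplings are fixed to zero.  The intercept b is always free (one
    global value across blocks, as a single model must describe every
    spin sector).  Upper-triangle matrix elements of every block enter
    with equal weight.  Raises on a rank-deficient design, naming the
    confounded parameter combinations.
    """
    spins = [HalfInt(s) for s in site_spins]
    k = len(spins)
    names = _free_param_list(k, free)
    schemes_totals = []
    for blk in blocks:
        first = parse_label(blk.basis_labels[0])
        scheme = "local" if isinstance(first, LocalCSF) else "tree"
        schemes_totals.append((scheme, first.total_spin))

    # design columns: d(H_block)/d(param) elements, then the intercept
    rows_y, rows_X = [], []
    slices = []
    for blk, (scheme, total) in zip(blocks, schemes_totals):
        d = blk.dim
        iu = np.triu_indices(d)
        y = blk.matrix[iu]
        cols = []
        for name in names:
            tag, i, j = name[0], int(name[1]) - 1, int(name[2]) - 1
            unit = ModelParams.from_pairs(
                k, {(i, j): 1.0} if tag == "J" else None,
                {(i, j): 1.0} if tag == "K" else None)
            coeff = model_in_coupled_basis(spins, unit, scheme, total)
            if tuple(coeff.basis_labels) != tuple(blk.basis_labels):
                raise ValueError("block basis labels do not match the model "
                                 f"basis for S_tot={total}")
            cols.append(coeff.matrix[iu])
        cols.append(np.eye(d)[iu])  # intercept on the identity
        rows_y.append(y)
        rows_X.append(np.column_stack(cols))
        slices.append((iu, d))
    y = np.concatenate(rows_y)
    X = np.vstack(rows_X)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, vt = np.linalg.svd(X)
        null = vt[rank:]
        combos = []
        labels = list(names) + ["b"]
        for vec in null:
            combos.append(" + ".join(f"{c:+.2f}*{labels[i]}"
                                     for i, c in enumerate(vec)
                                     if abs(c) > 1e-8))
        raise ValueError("rank-deficient design; confounded combinations: "
                         + "; ".join(combos))
    theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ theta
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    params = ModelParams.from_pairs(k, b=float(theta[-1]))
    Jm, Km = params.J.copy(), params.K.copy()
    for name, value in zip(names, theta[:-1]):
        tag, i, j = name[0], int(name[1]) - 1, int(name[2]) - 1
        (Jm if tag == "J" else Km)[i, j] = value
        (Jm if tag == "J" else Km)[j, i] = value
    params = ModelParams(Jm, Km, float(theta[-1]))

    residuals = []
    offset = 0
    for (iu, d) in slices:
        n_el = len(iu[0])
        res = np.zeros((d, d))
        res[iu] = (y - fitted)[offset:offset + n_el]
        res = res + np.triu(res, 1).T
        residuals.append(res)
        offset += n_el
    return FitResult(params, r2, tuple(residuals), tuple(names))


def sparsity_measures(coefficients: np.ndarray,
                      norm_tol: float = 1.0e-8) -> tuple[float, float]:
    """L1 norm and inverse participation ratio of a normalized CI vector.

    L1 = sum |c_i| (1 for a single-CSF state, sqrt(d) for uniform spread
    over d CSFs); IPR = sum c_i^4 (1 for a single CSF, 1/d for uniform
    spread).  Small L1 and large IPR both indicate a sparse wave
    function.  Raises on an unnormalized input — no silent rescaling.
    """
    c = np.asarray(coefficients, dtype=float).ravel()
    norm = float(np.linalg.norm(c))
    if abs(norm - 1.0) > norm_tol:
        raise ValueError(f"coefficient vector is not normalized "
                         f"(||c|| = {norm:.10f})")
    return float(np.sum(np.abs(c))), float(np.sum(c ** 4))
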