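# Methods

## Problem

Polynuclear transition-metal clusters (manganese cubanes, iron–sulfur
cages, the cofactors of photosystem II or nitrogenase) host several
magnetic sites with local spins S_i ≥ 1.  Their low-energy physics is
usually summarized by a Heisenberg–Dirac–Van Vleck model,

    H = Σ_{i<j} J_ij Ŝ_i·Ŝ_j + K_ij (Ŝ_i·Ŝ_j)² + b,

with J > 0 antiferromagnetic and energies in cm⁻¹ (the `j_sign` flag
flips the convention).  Extracting the couplings J_ij, K_ij from a
spin-adapted configuration-interaction (CI) calculation requires
expressing CI eigenvectors in a basis in which the model's local spin
quantum numbers are defined.  Quantum-chemistry codes deliver CI vectors
over *genealogical* configuration state functions (CSFs): electrons
1..N coupled one at a time, each CSF a branching-diagram path of
cumulative spins.  The model lives on *site-coupled* states: electrons
pre-coupled within each site to site spins S̄_i, the site spins then
chained (local sequential scheme |L⟩) or, for four sites, paired as
((AB)(CD)) (binary-tree scheme |T⟩).  The package's core is the exact
unitary change of basis between these schemes.

## Recoupling coefficients

Both the genealogical scheme |C⟩ and the local scheme |L⟩ couple the
same leading electron subsets, which forces Kronecker deltas: the
intra-site path of site 1 must equal the head of the genealogical path,
and the genealogical cumulative spin at each site boundary must equal
the corresponding running coupling of the chain.  The rest of ⟨C|L⟩
is a closed product built from the elementary recoupling bracket

    ⟨(j₁ j₂) J₁₂, j₃; J | j₁, (j₂ j₃) J₂₃; J⟩ = W̃(j₁, j₂, J, j₃; J₁₂, J₂₃),

where W̃(a,b,c,d; e,f) = √((2e+1)(2f+1)) · W(a b c d; e f) is the
Racah coefficient with both intermediate dimension factors absorbed.
With this normalization no phase survives: applying the bracket once
per electron gives

    ⟨C|L⟩ = Δ(site-1 path) · Π_i Δ(boundary_i) ·
            Π_{i≥2} Π_{m=2}^{n_i} W̃(T_{i-1}, V_{m-1}, U_m, ½; U_{m-1}, V_m)

with T the running couplings, V the intra-site and U the cross-boundary
genealogical cumulative spins — (k−1)(n−1) weighted Racah symbols for a
chain of k sites of n electrons.  The derivation nowhere assumes equal
electron counts, so the same product handles inequivalent sites.  The
(((AB)C)D) → ((AB)(CD)) tree transform shares S_AB with the chain
(one more delta) and reduces to the single symbol
W̃(S_AB, S_C, S_tot, S_D; T₃, S_CD).

Correctness is arbitrated by an independent brute-force oracle: the
resolution of the identity over all uncoupled product states, evaluated
as sums of Clebsch–Gordan products in the stretched projection block.
The closed form and the oracle agree to < 10⁻¹² on every block of
(k,n) ∈ {(2,2),(2,3),(3,2),(3,3),(2,4)} and on a mixed (3,2)-electron
two-site system; this agreement is asserted in the test suite, and the
convention-independent oracle wins by design should the two ever
disagree.

## Exact arithmetic

All spins are doubled integers end-to-end (`HalfInt`), making triangle
and parity selection integer-exact.  Symbol values are exact radicals
q·√r with q, r rational (`SymbolValue`), computed from Racah's
single-sum formulas with `fractions.Fraction`; square factors are
extracted by trial division, which is exhaustive because every integer
involved stems from factorials of small arguments.  Floats are a view
of the exact value, never the source of truth, so a *structural* zero
(violated delta or triangle, or an accidental Racah zero) is decidable
exactly.  Transformation matrices between standard/local and local/tree
bases carry their exact entries; standard↔tree is their float
composition.  Support counts (how many basis functions carry a state)
are taken on exact entries.  One structural fact makes even composed
supports exact: a standard CSF overlaps at most one local chain (the
boundary deltas fix T₂…T_k), so distinct chains have disjoint standard
supports and no cancellation can occur when chains are mixed.

The Condon–Shortley phase convention is fixed globally.  CI vectors
exported from unitary-group (GUGA) codes differ from the genealogical
convention by a sign on levels with step value 2 or 3; the adapter
applies (−1)^{b_l} per such level (b_l = twice the cumulative spin after
level l).  This diagonal sign map is validated by norm/orthogonality
round-trips; an external ab initio cross-check is out of scope here, so
consumers of real GUGA dumps should verify the convention against one
known coefficient of their code.

## Effective Hamiltonian and fit

Given CI eigenpairs of one total-spin block, the pipeline (i) reads the
vector over standard CSF labels, (ii) recouples into the local or tree
scheme, (iii) projects onto the model space — the Hund manifold, every
site at maximal spin — recording each root's retained norm ‖Pψ‖²,
(iv) orthonormalizes the projections, and (v) inverts the spectral
decomposition, H_eff = Σ_i |ψ̃_i⟩E_i⟨ψ̃_i|.  Orthonormalization is
Löwdin-symmetric (S^{−1/2}), the des Cloizeaux choice: it keeps the
orthonormalized vectors closest to the projections and makes H_eff
Hermitian.  Retained norms below 0.9 are logged, not rejected — a
reduced magnetic-manifold weight is expected when ligand orbitals are
correlated.

Couplings are obtained from a linear least-squares fit of the numerical
blocks to the analytic model matrix: design columns are the exact
coefficient of each free J_ij/K_ij on every upper-triangle element,
plus one global intercept b on the identity.  Blocks are fitted jointly
with equal element weights (per-block weighting was left out: in the
near-exact regime R² ≈ 1 the weighting is immaterial, and a single
model must describe all spin sectors anyway).  Rank deficiency is
reported with the confounded parameter combinations.  R² is the
coefficient of determination over the stacked elements.  Roots closer
than 0.5 cm⁻¹ are treated as degenerate only in the sense that all
comparisons run on H_eff itself, which is invariant under mixing within
a degenerate pair — individual degenerate vectors are never compared.

For three S = 3/2 sites the S_tot = 3/2 block is also produced
symbolically (sympy, exact Clebsch–Gordan), an arithmetic path
independent of the float construction; the two agree to 10⁻¹⁰ over
random parameter draws.  Two structural facts of that block are
asserted: J₁₃ = J₂₃ with K = 0 conserves the pair spin S₁₂ and
diagonalizes the block, and the ⟨S₁₂=0|H|S₁₂=3⟩ element vanishes
identically (bilinear and biquadratic couplings move S₁₂ by at most
two).

## Synthetic fixtures

The generator emulates what a CASSCF/RASSCF-type calculation hands the
pipeline, without any electronic-structure content.  On the full local
basis of a block, the spin model acts on the Hund manifold; non-Hund
CSFs sit a gap Δ higher (Hund's-rule penalty, default Δ = 10⁴ cm⁻¹,
the intra-atomic exchange scale); a seeded random symmetric coupling of
total per-root strength t (default 10² cm⁻¹) admixes them.  Matrix
elements are drawn N(0, t²/d_bath) so each root's discarded norm is
O(t²/Δ²) independent of the bath size.  The full matrix is
diagonalized, the model-dimension roots with the largest Hund weight
are selected, and their vectors are recoupled to the standard basis —
a complete, deterministic (seeded) synthetic input.

Default parameters are the three-site manganese-cubane values
J₁₂ = −6.6, J₁₃ = −27.7, J₂₃ = −20.0 cm⁻¹, K = 0, b = −0.01 cm⁻¹.
With t = 0 the pipeline returns the couplings at machine precision;
at t/Δ = 0.01 the median relative error of the recovered J over seeds
1–20 is ≈ 0.3% (the acceptance suite requires < 5%).  What the fixture
does *not* emulate: spatial-orbital relaxation, doubly occupied or
charge-transfer configurations with their own structure (the bath is
white noise), and size-consistent energy scales — so passing tests
demonstrate the correctness of the recoupling/extraction machinery, not
the accuracy of any ab initio protocol.

## Combinatorial benchmarks

Problem sizes used throughout are desk-scale: the largest recoupling
block is 20 electrons (170 CSFs at S_tot = 8), the largest product
space 4⁴ = 256 (four S = 3/2 sites) for models and 1296 (four S = 5/2)
within reach of the guard.  Two counts serve as fixed benchmarks for
the four-site S = 5/2, S_tot = 8 system: the branching diagram has 170
open-shell CSFs, of which 105 pass the first-site Hund waypoint
(5 electrons at S = 5/2); the six-state Hund manifold occupies exactly
six CSFs in the |L⟩ and |T⟩ schemes; and the lowest root of the
pair-symmetric model — the single tree CSF |S_AB=4, S_CD=4⟩ — spreads
over exactly 50 standard CSFs.  The six local chains have pairwise
disjoint standard supports of 10/25/25/10/25/10 (union 105), so
"support of a root" is well defined independent of mixing within the
chains it touches.

## Numerical choices and limitations

* Basis orderings are lexicographic over doubled-integer tuples;
  transformation matrices are bit-for-bit reproducible.
* Float support thresholds (1e-10) are used only where a composed
  (standard↔tree) float matrix is inspected; physics decisions use
  exact arithmetic.
* Symbols are memoized on doubled-integer keys; the 170×6 exact Hund
  block evaluates in well under a second.
* Dense matrices only; the dimension guard (10⁵) rejects product spaces
  that would not be "trivially dense-diagonalizable".
* Out of scope: 9j and higher symbols, Serber pair functions, Bloch
  (non-Hermitian) or quasi-degenerate-perturbative effective
  Hamiltonians, anisotropic/Dzyaloshinskii–Moriya terms, and any ab
  initio electronic structure.  Tree CSFs are implemented for exactly
  four sites.
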