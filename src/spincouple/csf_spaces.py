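"""Spin-coupling bases: enumeration, counting and label grammar.

Three coupling schemes are supported for a system of magnetic sites:

* standard genealogical CSFs ``|C>`` — electrons 1..N coupled one at a
  time; a CSF is a branching-diagram path of cumulative spins,
* local sequential CSFs ``|L>`` — electrons pre-coupled within each site
  to site spins, site spins then coupled along a chain,
* binary-tree CSFs ``|T>`` — four sites coupled pairwise, (AB) and (CD),
  the two pair spins then coupled to the total spin.

All bases of one (N, S_tot) block have equal cardinality; orderings are
lexicographic over doubled-integer tuples so that transformation
matrices are bit-for-bit reproducible.

Label grammar (round-trips through :func:`parse_label` / ``.label``):

* standard: ``C:1/2,1,3/2,...`` (cumulative spins),
* local: ``L:[3/2,3/2,3/2];0,3/2`` (site spins; then the running
  couplings T_2..T_k — T_1 is the first site spin).  Electron-resolved
  site spins carry their intra-site genealogical path in parentheses:
  ``L:[3/2(1/2,1,3/2),...];0,3/2``,
* tree: ``T:[5/2x4];3,5;8`` (four site spins, ``x4`` shorthand for
  repetition; the pair spins S_AB,S_CD; the total spin).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence, Union

from .su2_algebra import HALF, HalfInt, HalfIntLike, triangle_ok

__all__ = [
    "SystemSpec",
    "StandardCSF",
    "LocalCSF",
    "TreeCSF",
    "UncoupledState",
    "enumerate_standard",
    "count_standard",
    "enumerate_local",
    "enumerate_tree",
    "hund_manifold",
    "parse_label",
]


def _tuple_halfint(values: Iterable[HalfIntLike]) -> tuple[HalfInt, ...]:
    return tuple(HalfInt(v) for v in values)


@dataclass(frozen=True)
class SystemSpec:
    """A multi-site magnetic system and the total-spin block of interest.

    Two flavours exist.  *Electron-resolved*: every site carries
    ``electrons_per_site[i]`` unpaired electrons; site spins range over
    everything those electrons can couple to (this is the flavour CSF
    recoupling of CI vectors needs).  *Spin-only*: each site is a rigid
    spin ``site_spins[i]`` (the flavour a Heisenberg model lives on).
    """

    total_spin: HalfInt
    electrons_per_site: Optional[tuple[int, ...]] = None
    site_spins: Optional[tuple[HalfInt, ...]] = None

    def __post_init__(self):
        object.__setattr__(self, "total_spin", HalfInt(self.total_spin))
        if (self.electrons_per_site is None) == (self.site_spins is None):
            raise ValueError("give exactly one of electrons_per_site / site_spins")
        if self.electrons_per_site is not None:
            eps = tuple(int(n) for n in self.electrons_per_site)
            if len(eps) < 1 or any(n < 1 for n in eps):
                raise ValueError("need >= 1 site with >= 1 electron each")
            object.__setattr__(self, "electrons_per_site", eps)
        else:
            spins = _tuple_halfint(self.site_spins)
            if len(spins) < 1 or any(s.twice <= 0 for s in spins):
                raise ValueError("site spins must be positive")
            object.__setattr__(self, "site_spins", spins)

    @staticmethod
    def equal_chain(k: int, n: int, total_spin: HalfIntLike) -> "SystemSpec":
        """k sites of n unpaired electrons each (the equal-spin chain)."""
        return SystemSpec(HalfInt(total_spin), electrons_per_site=(int(n),) * int(k))

    @staticmethod
    def from_site_spins(spins: Sequence[HalfIntLike],
                        total_spin: HalfIntLike) -> "SystemSpec":
        return SystemSpec(HalfInt(total_spin), site_spins=_tuple_halfint(spins))

    @property
    def electron_resolved(self) -> bool:
        return self.electrons_per_site is not None

    @property
    def n_sites(self) -> int:
        return len(self.electrons_per_site if self.electron_resolved
                   else self.site_spins)

    @property
    def n_electrons(self) -> int:
        if not self.electron_resolved:
            raise ValueError("spin-only system has no electron count")
        return sum(self.electrons_per_site)

    @property
    def max_site_spins(self) -> tuple[HalfInt, ...]:
        """Hund's-rule (maximal) spin of every site."""
        if self.electron_resolved:
            return tuple(HalfInt(twice=n) for n in self.electrons_per_site)
        return self.site_spins

    def site_boundaries(self) -> tuple[int, ...]:
        """Cumulative electron counts at the end of each site."""
        return tuple(itertools.accumulate(self.electrons_per_site))


def _fmt_path(path: Sequence[HalfInt]) -> str:
    return ",".join(str(s) for s in path)


def _parse_path(text: str) -> tuple[HalfInt, ...]:
    return tuple(HalfInt.parse(tok) for tok in text.split(",") if tok != "")


@dataclass(frozen=True, order=True)
class StandardCSF:
    """Genealogical CSF: the branching-diagram path of cumulative spins.

    ``cumulative[j-1]`` is the total spin of electrons 1..j; the path
    starts at 1/2, moves by ±1/2, never dips below zero and ends at the
    block's total spin.
    """

    cumulative: tuple[HalfInt, ...]

    def __post_init__(self):
        path = _tuple_halfint(self.cumulative)
        object.__setattr__(self, "cumulative", path)
        if not path or path[0] != HALF:
            raise ValueError("genealogical path must start at 1/2")
        for prev, cur in zip(path, path[1:]):
            if abs(cur.twice - prev.twice) != 1 or cur.twice < 0:
                raise ValueError("path steps must be +-1/2 and stay >= 0")

    @property
    def n_electrons(self) -> int:
        return len(self.cumulative)

    @property
    def total_spin(self) -> HalfInt:
        return self.cumulative[-1]

    @property
    def label(self) -> str:
        return "C:" + _fmt_path(self.cumulative)

    def sort_key(self) -> tuple[int, ...]:
        return tuple(s.twice for s in self.cumulative)

    @staticmethod
    def parse(text: str) -> "StandardCSF":
        if not text.startswith("C:"):
            raise ValueError(f"not a standard-scheme label: {text!r}")
        return StandardCSF(_parse_path(text[2:]))


def _fmt_site(spin: HalfInt, path: Optional[tuple[HalfInt, ...]]) -> str:
    if path is None:
        return str(spin)
    return f"{spin}({_fmt_path(path)})"


def _parse_site(tok: str) -> tuple[HalfInt, Optional[tuple[HalfInt, ...]]]:
    if "(" in tok:
        spin_text, rest = tok.split("(", 1)
        if not rest.endswith(")"):
            raise ValueError(f"malformed site token {tok!r}")
        path = _parse_path(rest[:-1])
        return HalfInt.parse(spin_text), path
    return HalfInt.parse(tok), None


@dataclass(frozen=True)
class LocalCSF:
    """Local sequential CSF: site spins coupled along a chain.

    ``couplings[i-1]`` is the running coupling of sites 1..i (so
    ``couplings[0] == site_spins[0]`` and the last entry is the total
    spin).  For electron-resolved work every site additionally carries
    its intra-site genealogical path ``intra_paths[i]`` ending at the
    site spin; a site at maximal (Hund) spin has the unique stretched
    path.
    """

    site_spins: tuple[HalfInt, ...]
    couplings: tuple[HalfInt, ...]
    intra_paths: Optional[tuple[tuple[HalfInt, ...], ...]] = None

    def __post_init__(self):
        spins = _tuple_halfint(self.site_spins)
        coup = _tuple_halfint(self.couplings)
        object.__setattr__(self, "site_spins", spins)
        object.__setattr__(self, "couplings", coup)
        if len(coup) != len(spins):
            raise ValueError("need one running coupling per site")
        if coup[0] != spins[0]:
            raise ValueError("first running coupling must equal the first site spin")
        for i in range(1, len(spins)):
            if not triangle_ok(coup[i - 1], spins[i], coup[i]):
                raise ValueError(
                    f"triangle violated at site {i + 1}: "
                    f"({coup[i - 1]}, {spins[i]}, {coup[i]})")
        if self.intra_paths is not None:
            paths = tuple(_tuple_halfint(p) for p in self.intra_paths)
            object.__setattr__(self, "intra_paths", paths)
            if len(paths) != len(spins):
                raise ValueError("need one intra-site path per site")
            for spin, path in zip(spins, paths):
                StandardCSF(path)  # validates the path shape
                if path[-1] != spin:
                    raise ValueError("intra-site path must end at the site spin")

    @property
    def n_sites(self) -> int:
        return len(self.site_spins)

    @property
    def total_spin(self) -> HalfInt:
        return self.couplings[-1]

    @property
    def is_hund(self) -> bool:
        """True iff every site spin is maximal for its electron count."""
        if self.intra_paths is None:
            return True
        return all(s.twice == len(p) for s, p in
                   zip(self.site_spins, self.intra_paths))

    @property
    def label(self) -> str:
        sites = ",".join(
            _fmt_site(s, None if self.intra_paths is None else self.intra_paths[i])
            for i, s in enumerate(self.site_spins))
        tail = _fmt_path(self.couplings[1:])
        return f"L:[{sites}];{tail}"

    def sort_key(self) -> tuple:
        paths = self.intra_paths or ()
        return (tuple(s.twice for s in self.site_spins),
                tuple(s.twice for s in self.couplings),
                tuple(tuple(s.twice for s in p) for p in paths))

    @staticmethod
    def parse(text: str) -> "LocalCSF":
        if not text.startswith("L:["):
            raise ValueError(f"not a local-scheme label: {text!r}")
        body = text[3:]
        close = body.index("]")
        site_part, tail = body[:close], body[close + 1:]
        if not tail.startswith(";"):
            raise ValueError(f"missing couplings in {text!r}")
        # split site tokens at commas outside parentheses
        tokens, depth, cur = [], 0, ""
        for ch in site_part:
            if ch == "," and depth == 0:
                tokens.append(cur)
                cur = ""
                continue
            depth += ch == "("
            depth -= ch == ")"
            cur += ch
        tokens.append(cur)
        parsed = [_parse_site(tok) for tok in tokens]
        spins = tuple(s for s, _ in parsed)
        paths = tuple(p for _, p in parsed)
        coup = (spins[0],) + _parse_path(tail[1:])
        if all(p is None for p in paths):
            return LocalCSF(spins, coup)
        if any(p is None for p in paths):
            raise ValueError(f"mixed site tokens (with/without paths) in {text!r}")
        return LocalCSF(spins, coup, paths)


@dataclass(frozen=True)
class TreeCSF:
    """Binary-tree CSF for four sites: |S_AB, S_CD; S_tot>."""

    site_spins: tuple[HalfInt, ...]
    s_ab: HalfInt
    s_cd: HalfInt
    total_spin: HalfInt
    intra_paths: Optional[tuple[tuple[HalfInt, ...], ...]] = None

    def __post_init__(self):
        spins = _tuple_halfint(self.site_spins)
        object.__setattr__(self, "site_spins", spins)
        object.__setattr__(self, "s_ab", HalfInt(self.s_ab))
        object.__setattr__(self, "s_cd", HalfInt(self.s_cd))
        object.__setattr__(self, "total_spin", HalfInt(self.total_spin))
        if len(spins) != 4:
            raise ValueError("tree scheme is defined for exactly four sites")
        if not triangle_ok(spins[0], spins[1], self.s_ab):
            raise ValueError("triangle (S_A, S_B, S_AB) violated")
        if not triangle_ok(spins[2], spins[3], self.s_cd):
            raise ValueError("triangle (S_C, S_D, S_CD) violated")
        if not triangle_ok(self.s_ab, self.s_cd, self.total_spin):
            raise ValueError("triangle (S_AB, S_CD, S_tot) violated")
        if self.intra_paths is not None:
            paths = tuple(_tuple_halfint(p) for p in self.intra_paths)
            object.__setattr__(self, "intra_paths", paths)
            for spin, path in zip(spins, paths):
                StandardCSF(path)
                if path[-1] != spin:
                    raise ValueError("intra-site path must end at the site spin")

    @property
    def label(self) -> str:
        if self.intra_paths is None and len(set(s.twice for s in self.site_spins)) == 1:
            sites = f"{self.site_spins[0]}x4"
        else:
            sites = ",".join(
                _fmt_site(s, None if self.intra_paths is None else self.intra_paths[i])
                for i, s in enumerate(self.site_spins))
        return f"T:[{sites}];{self.s_ab},{self.s_cd};{self.total_spin}"

    def sort_key(self) -> tuple:
        paths = self.intra_paths or ()
        return (tuple(s.twice for s in self.site_spins),
                (self.s_ab.twice, self.s_cd.twice),
                tuple(tuple(s.twice for s in p) for p in paths))

    @staticmethod
    def parse(text: str) -> "TreeCSF":
        if not text.startswith("T:["):
            raise ValueError(f"not a tree-scheme label: {text!r}")
        body = text[3:]
        close = body.index("]")
        site_part, tail = body[:close], body[close + 1:]
        parts = tail.lstrip(";").split(";")
        if len(parts) != 2:
            raise ValueError(f"malformed tree label {text!r}")
        pair_part, total_part = parts
        if "x" in site_part and "(" not in site_part:
            spin_text, count = site_part.split("x")
            spins = (HalfInt.parse(spin_text),) * int(count)
            paths = None
        else:
            tokens, depth, cur = [], 0, ""
            for ch in site_part:
                if ch == "," and depth == 0:
                    tokens.append(cur)
                    cur = ""
                    continue
                depth += ch == "("
                depth -= ch == ")"
                cur += ch
            tokens.append(cur)
            parsed = [_parse_site(tok) for tok in tokens]
            spins = tuple(s for s, _ in parsed)
            paths = tuple(p for _, p in parsed)
            if all(p is None for p in paths):
                paths = None
        s_ab, s_cd = _parse_path(pair_part)
        return TreeCSF(spins, s_ab, s_cd, HalfInt.parse(total_part),
                       intra_paths=paths)


@dataclass(frozen=True)
class UncoupledState:
    """Product state of z-projections (per electron or per site)."""

    projections: tuple[HalfInt, ...]

    def __post_init__(self):
        object.__setattr__(self, "projections", _tuple_halfint(self.projections))

    @property
    def total_m(self) -> HalfInt:
        return HalfInt(twice=sum(m.twice for m in self.projections))


CSF = Union[StandardCSF, LocalCSF, TreeCSF]


def parse_label(text: str) -> CSF:
    """Parse any CSF label (C:/L:/T: grammar) into its CSF object."""
    if text.startswith("C:"):
        return StandardCSF.parse(text)
    if text.startswith("L:"):
        return LocalCSF.parse(text)
    if text.startswith("T:"):
        return TreeCSF.parse(text)
    raise ValueError(f"unknown CSF label scheme: {text!r}")


# ---------------------------------------------------------------------------
# branching-diagram enumeration and counting


def _normalize_constraints(
        constraints: Sequence[tuple[int, HalfIntLike]] | None,
        n_electrons: int) -> dict[int, int]:
    """Map 1-based electron positions to required doubled cumulative spins."""
    out: dict[int, int] = {}
    for pos, spin in (constraints or ()):
        pos = int(pos)
        if not 1 <= pos <= n_electrons:
            raise ValueError(f"waypoint position {pos} outside 1..{n_electrons}")
        tw = HalfInt(spin).twice
        if pos in out and out[pos] != tw:
            return {pos: -1}  # contradictory waypoints: empty basis
        out[pos] = tw
    return out


def enumerate_standard(
        n_electrons: int, total_spin: HalfIntLike,
        constraints: Sequence[tuple[int, HalfIntLike]] | None = None,
) -> list[StandardCSF]:
    """All genealogical CSFs of an (N, S_tot) block, lexicographic order.

    ``constraints`` is a list of waypoints ``(position, spin)`` forcing
    the cumulative spin after ``position`` electrons; Hund's rule on the
    first site of ``n`` electrons is the waypoint ``(n, n/2)``.  An
    unreachable total spin yields an empty list.
    """
    n_electrons = int(n_electrons)
    target = HalfInt(total_spin).twice
    if n_electrons < 1 or target < 0 or (n_electrons - target) % 2:
        return []
    waypoints = _normalize_constraints(constraints, n_electrons)

    paths: list[StandardCSF] = []
    path = [1]
    if waypoints.get(1, 1) != 1:
        return []

    def extend(j: int) -> None:
        if j == n_electrons:
            if path[-1] == target:
                paths.append(StandardCSF(
                    tuple(HalfInt(twice=t) for t in path)))
            return
        remaining = n_electrons - j - 1
        for step in (-1, 1):  # ascending doubled value => lexicographic order
            nxt = path[-1] + step
            if nxt < 0:
                continue
            if abs(nxt - target) > remaining:
                continue
            if waypoints.get(j + 1, nxt) != nxt:
                continue
            path.append(nxt)
            extend(j + 1)
            path.pop()

    extend(1)
    return paths


def count_standard(
        n_electrons: int, total_spin: HalfIntLike,
        constraints: Sequence[tuple[int, HalfIntLike]] | None = None) -> int:
    """Number of genealogical CSFs, by dynamic programming on the lattice.

    Equals ``len(enumerate_standard(...))`` but runs in O(N^2) so large
    branching diagrams are cheap.
    """
    n_electrons = int(n_electrons)
    target = HalfInt(total_spin).twice
    if n_electrons < 1 or target < 0 or (n_electrons - target) % 2:
        return 0
    waypoints = _normalize_constraints(constraints, n_electrons)
    # counts[t] = number of admissible paths reaching doubled spin t after j electrons
    counts = {1: 1}
    if waypoints.get(1, 1) != 1:
        return 0
    for j in range(2, n_electrons + 1):
        nxt: dict[int, int] = {}
        for t, c in counts.items():
            for step in (-1, 1):
                u = t + step
                if u < 0:
                    continue
                if waypoints.get(j, u) != u:
                    continue
                nxt[u] = nxt.get(u, 0) + c
        counts = nxt
    return counts.get(target, 0)


# ---------------------------------------------------------------------------
# local sequential and binary-tree bases


@lru_cache(maxsize=None)
def _site_paths(n: int) -> tuple[tuple[tuple[HalfInt, ...], ...], ...]:
    """All intra-site genealogical paths for n electrons, grouped later."""
    paths = []
    for twice_s in range(n % 2, n + 1, 2):
        paths.extend(p.cumulative for p in
                     enumerate_standard(n, HalfInt(twice=twice_s)))
    return tuple(paths)


def _coupling_chains(site_spins: Sequence[HalfInt],
                     total: HalfInt) -> list[tuple[HalfInt, ...]]:
    """All running-coupling chains T_1..T_k over fixed site spins."""
    k = len(site_spins)
    chains: list[tuple[HalfInt, ...]] = []
    chain = [site_spins[0]]

    def extend(i: int) -> None:
        if i == k:
            if chain[-1] == total:
                chains.append(tuple(chain))
            return
        t_prev, s_next = chain[-1], site_spins[i]
        lo = abs(t_prev.twice - s_next.twice)
        hi = t_prev.twice + s_next.twice
        remaining = sum(site_spins[j].twice for j in range(i + 1, k))
        for t in range(lo, hi + 1, 2):
            if abs(t - total.twice) > remaining:
                continue
            chain.append(HalfInt(twice=t))
            extend(i + 1)
            chain.pop()

    extend(1)
    return chains


def enumerate_local(spec: SystemSpec) -> list[LocalCSF]:
    """All local sequential CSFs of the block, lexicographically ordered.

    For an electron-resolved spec the enumeration runs over every
    intra-site genealogical path (so the basis has the same dimension as
    the standard one); for a spin-only spec only the coupling chains
    vary.
    """
    out: list[LocalCSF] = []
    if spec.electron_resolved:
        per_site = [_site_paths(n) for n in spec.electrons_per_site]
        for combo in itertools.product(*per_site):
            spins = tuple(p[-1] for p in combo)
            for chain in _coupling_chains(spins, spec.total_spin):
                out.append(LocalCSF(spins, chain, intra_paths=tuple(combo)))
    else:
        for chain in _coupling_chains(spec.site_spins, spec.total_spin):
            out.append(LocalCSF(spec.site_spins, chain))
    out.sort(key=LocalCSF.sort_key)
    return out


def enumerate_tree(spec: SystemSpec) -> list[TreeCSF]:
    """All binary-tree CSFs; requires exactly four sites."""
    if spec.n_sites != 4:
        raise ValueError("tree scheme is defined for exactly four sites")
    out: list[TreeCSF] = []

    def pairs_for(spins: tuple[HalfInt, ...],
                  paths: Optional[tuple[tuple[HalfInt, ...], ...]]) -> None:
        sa, sb, sc, sd = spins
        for tab in range(abs(sa.twice - sb.twice), sa.twice + sb.twice + 1, 2):
            for tcd in range(abs(sc.twice - sd.twice), sc.twice + sd.twice + 1, 2):
                if triangle_ok(HalfInt(twice=tab), HalfInt(twice=tcd),
                               spec.total_spin):
                    out.append(TreeCSF(spins, HalfInt(twice=tab),
                                       HalfInt(twice=tcd), spec.total_spin,
                                       intra_paths=paths))

    if spec.electron_resolved:
        per_site = [_site_paths(n) for n in spec.electrons_per_site]
        for combo in itertools.product(*per_site):
            pairs_for(tuple(p[-1] for p in combo), tuple(combo))
    else:
        pairs_for(spec.site_spins, None)
    out.sort(key=TreeCSF.sort_key)
    return out


def hund_manifold(spec: SystemSpec) -> list[LocalCSF]:
    """The local CSFs with every site spin maximal (Hund's rule).

    For an electron-resolved spec each site then carries the unique
    stretched intra-site path; empty when the total spin is not
    reachable from maximal site spins.
    """
    if spec.electron_resolved:
        spins = spec.max_site_spins
        paths = tuple(tuple(HalfInt(twice=t) for t in range(1, n + 1))
                      for n in spec.electrons_per_site)
    else:
        spins, paths = spec.site_spins, None
    return [LocalCSF(spins, chain, intra_paths=paths)
            for chain in _coupling_chains(list(spins), spec.total_spin)]
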