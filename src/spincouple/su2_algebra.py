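"""Exact SU(2) coupling algebra over half-integer angular momenta.

Provides the primitive symbols used by all recoupling machinery:
Clebsch-Gordan coefficients, Wigner 3j and 6j symbols, Racah W
coefficients and the dimension-weighted Racah symbol W-tilde that
recoupling products are written in.

Every spin is carried as a doubled integer (:class:`HalfInt`), so triangle
and parity selection rules are integer-exact.  Symbol values are computed
in exact rational arithmetic as ``q * sqrt(r)`` with ``q, r`` rational
(:class:`SymbolValue`); the float view is derived from the exact value and
is never the source of truth, which makes "structural zero" decidable.

The Condon-Shortley phase convention is used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache, total_ordering
from typing import Union

__all__ = [
    "HalfInt",
    "SymbolValue",
    "triangle_ok",
    "clebsch_gordan",
    "wigner_3j",
    "wigner_6j",
    "racah_w",
    "weighted_w",
]

HalfIntLike = Union["HalfInt", int, Fraction, str]


@total_ordering
class HalfInt:
    """An exact half-integer ``j``, stored as the doubled integer ``2j``.

    Supports the arithmetic needed for spin bookkeeping (sum, difference,
    comparison) and parses/prints the conventional fraction notation
    ("3/2", "2").  Projections ``m`` of a spin ``j`` satisfy ``|m| <= j``
    and ``j - m`` integer; see :meth:`valid_projection`.
    """

    __slots__ = ("twice",)

    def __init__(self, value: HalfIntLike = 0, *, twice: int | None = None):
        if twice is not None:
            self.twice = int(twice)
            return
        if isinstance(value, HalfInt):
            self.twice = value.twice
        elif isinstance(value, int):
            self.twice = 2 * value
        elif isinstance(value, Fraction):
            doubled = 2 * value
            if doubled.denominator != 1:
                raise ValueError(f"{value} is not a half-integer")
            self.twice = int(doubled)
        elif isinstance(value, str):
            self.twice = HalfInt.parse(value).twice
        else:
            raise TypeError(f"cannot build HalfInt from {type(value).__name__}")

    @staticmethod
    def from_twice(twice: int) -> "HalfInt":
        return HalfInt(twice=twice)

    @staticmethod
    def parse(text: str) -> "HalfInt":
        text = text.strip()
        if "/" in text:
            num, den = text.split("/")
            if int(den) != 2:
                frac = Fraction(int(num), int(den))
                return HalfInt(frac)
            return HalfInt(twice=int(num))
        return HalfInt(twice=2 * int(text))

    @property
    def as_fraction(self) -> Fraction:
        return Fraction(self.twice, 2)

    @property
    def is_integer(self) -> bool:
        return self.twice % 2 == 0

    def valid_projection(self, m: "HalfInt") -> bool:
        """True iff ``m`` is a legal z-projection of this spin."""
        return abs(m.twice) <= self.twice and (self.twice - m.twice) % 2 == 0

    def projections(self) -> list["HalfInt"]:
        """All projections m = j, j-1, ..., -j (descending)."""
        return [HalfInt(twice=t) for t in range(self.twice, -self.twice - 1, -2)]

    @property
    def multiplicity(self) -> int:
        """Dimension 2j+1 of the spin-j multiplet."""
        return self.twice + 1

    def __add__(self, other: HalfIntLike) -> "HalfInt":
        return HalfInt(twice=self.twice + HalfInt(other).twice)

    def __sub__(self, other: HalfIntLike) -> "HalfInt":
        return HalfInt(twice=self.twice - HalfInt(other).twice)

    def __neg__(self) -> "HalfInt":
        return HalfInt(twice=-self.twice)

    def __abs__(self) -> "HalfInt":
        return HalfInt(twice=abs(self.twice))

    def __eq__(self, other) -> bool:
        try:
            return self.twice == HalfInt(other).twice
        except (TypeError, ValueError):
            return NotImplemented

    def __lt__(self, other) -> bool:
        return self.twice < HalfInt(other).twice

    def __hash__(self) -> int:
        return hash(("HalfInt", self.twice))

    def __float__(self) -> float:
        return self.twice / 2.0

    def __str__(self) -> str:
        if self.twice % 2 == 0:
            return str(self.twice // 2)
        return f"{self.twice}/2"

    def __repr__(self) -> str:
        return f"HalfInt({self})"


HALF = HalfInt(twice=1)


def _square_free_split(n: int) -> tuple[int, int]:
    """Split n > 0 into (s, r) with n = s**2 * r and r square-free.

    All integers reaching this routine come from factorial ratios of
    small arguments, so trial division by small primes is exhaustive.
    """
    s, r = 1, 1
    d = 2
    while d * d <= n:
        if n % d == 0:
            power = 0
            while n % d == 0:
                n //= d
                power += 1
            s *= d ** (power // 2)
            if power % 2:
                r *= d
        d += 1 if d == 2 else 2
    return s, r * n


@dataclass(frozen=True)
class SymbolValue:
    """Exact value of an SU(2) coupling symbol: ``coeff * sqrt(radicand)``.

    ``coeff`` is a signed rational, ``radicand`` a non-negative rational
    kept square-free after normalization.  Closed under multiplication,
    which is all a recoupling product needs; addition is defined only for
    compatible radicands (used in same-radicand accumulations) and raises
    otherwise.  ``float(v)`` gives the float view.
    """

    coeff: Fraction
    radicand: Fraction = Fraction(1)

    @staticmethod
    def make(coeff: Fraction | int, radicand: Fraction | int = 1) -> "SymbolValue":
        coeff = Fraction(coeff)
        radicand = Fraction(radicand)
        if radicand < 0:
            raise ValueError("radicand must be non-negative")
        if coeff == 0 or radicand == 0:
            return SymbolValue(Fraction(0), Fraction(1))
        sn, rn = _square_free_split(radicand.numerator)
        sd, rd = _square_free_split(radicand.denominator)
        # sqrt(rn/rd) = sqrt(rn*rd)/rd
        return SymbolValue(coeff * Fraction(sn, sd * rd), Fraction(rn * rd))

    @staticmethod
    def zero() -> "SymbolValue":
        return SymbolValue(Fraction(0), Fraction(1))

    @staticmethod
    def one() -> "SymbolValue":
        return SymbolValue(Fraction(1), Fraction(1))

    @property
    def is_zero(self) -> bool:
        return self.coeff == 0

    def __mul__(self, other: "SymbolValue | int | Fraction") -> "SymbolValue":
        if isinstance(other, SymbolValue):
            return SymbolValue.make(self.coeff * other.coeff,
                                    self.radicand * other.radicand)
        return SymbolValue.make(self.coeff * Fraction(other), self.radicand)

    __rmul__ = __mul__

    def __neg__(self) -> "SymbolValue":
        return SymbolValue(-self.coeff, self.radicand)

    def __add__(self, other: "SymbolValue") -> "SymbolValue":
        if self.is_zero:
            return other
        if other.is_zero:
            return self
        if self.radicand != other.radicand:
            raise ValueError("cannot add SymbolValues with different radicands "
                             f"({self.radicand} vs {other.radicand})")
        return SymbolValue.make(self.coeff + other.coeff, self.radicand)

    def __float__(self) -> float:
        return float(self.coeff) * math.sqrt(float(self.radicand))

    def __str__(self) -> str:
        if self.radicand == 1:
            return str(self.coeff)
        return f"{self.coeff}*sqrt({self.radicand})"

    def to_sympy(self):
        """Exact sympy expression (lazy import; used by symbolic layers)."""
        import sympy
        return sympy.Rational(self.coeff.numerator, self.coeff.denominator) * \
            sympy.sqrt(sympy.Rational(self.radicand.numerator,
                                      self.radicand.denominator))


def _as_twice(j: HalfIntLike) -> int:
    return HalfInt(j).twice


def triangle_ok(a: HalfIntLike, b: HalfIntLike, c: HalfIntLike) -> bool:
    """Triangle condition |a-b| <= c <= a+b with integer perimeter.

    This is the selection rule every coupled pair of spins must satisfy;
    cumulative spins along a genealogical path fulfil it by construction.
    """
    ta, tb, tc = _as_twice(a), _as_twice(b), _as_twice(c)
    if min(ta, tb, tc) < 0:
        return False
    return abs(ta - tb) <= tc <= ta + tb and (ta + tb + tc) % 2 == 0


@lru_cache(maxsize=None)
def _factorial(n: int) -> int:
    return math.factorial(n)


def _fact_half(twice_n: int) -> int:
    """(n)! for a doubled-integer argument that must be a whole number."""
    if twice_n % 2:
        raise ValueError("factorial argument is not an integer")
    if twice_n < 0:
        raise ValueError("negative factorial argument")
    return _factorial(twice_n // 2)


def _triangle_factor(ta: int, tb: int, tc: int) -> Fraction:
    """Delta(abc) = (a+b-c)!(a-b+c)!(-a+b+c)! / (a+b+c+1)! on doubled args."""
    return Fraction(
        _fact_half(ta + tb - tc) * _fact_half(ta - tb + tc)
        * _fact_half(-ta + tb + tc),
        _fact_half(ta + tb + tc + 2),
    )


def _check_jm(tj: int, tm: int) -> None:
    if tj < 0 or abs(tm) > tj or (tj - tm) % 2:
        raise ValueError(f"invalid (j, m) pair (2j={tj}, 2m={tm})")


@lru_cache(maxsize=None)
def _cg_twice(tj1: int, tm1: int, tj2: int, tm2: int, tJ: int, tM: int) -> SymbolValue:
    if tm1 + tm2 != tM:
        return SymbolValue.zero()
    if not triangle_ok(HalfInt(twice=tj1), HalfInt(twice=tj2), HalfInt(twice=tJ)):
        return SymbolValue.zero()
    # Racah's closed form; all factorial arguments are integers here.
    pref = (Fraction(tJ + 1)
            * _triangle_factor(tj1, tj2, tJ)
            * Fraction(_fact_half(tJ + tM) * _fact_half(tJ - tM)
                       * _fact_half(tj1 - tm1) * _fact_half(tj1 + tm1)
                       * _fact_half(tj2 - tm2) * _fact_half(tj2 + tm2)))
    total = Fraction(0)
    # summation index k runs over all integers keeping factorial args >= 0
    k_min = max(0, -(tJ - tj2 + tm1), -(tJ - tj1 - tm2))
    k_max = min(tj1 + tj2 - tJ, tj1 - tm1, tj2 + tm2)
    for tk in range(k_min, k_max + 1, 2):
        term = Fraction(
            1,
            _fact_half(tk) * _fact_half(tj1 + tj2 - tJ - tk)
            * _fact_half(tj1 - tm1 - tk) * _fact_half(tj2 + tm2 - tk)
            * _fact_half(tJ - tj2 + tm1 + tk) * _fact_half(tJ - tj1 - tm2 + tk),
        )
        total += term if tk % 4 == 0 else -term
    if k_min % 2:  # parity mismatch: no integer summation index exists
        raise RuntimeError("internal CG index parity error")
    return SymbolValue.make(total) * SymbolValue.make(1, pref)


def clebsch_gordan(j1: HalfIntLike, m1: HalfIntLike, j2: HalfIntLike,
                   m2: HalfIntLike, J: HalfIntLike, M: HalfIntLike) -> SymbolValue:
    """Clebsch-Gordan coefficient <j1 m1; j2 m2 | J M> (Condon-Shortley).

    Returns exact zero when the projection or triangle selection rules
    fail; raises ``ValueError`` for a malformed (j, m) pair.
    """
    tj1, tm1 = _as_twice(j1), _as_twice(m1)
    tj2, tm2 = _as_twice(j2), _as_twice(m2)
    tJ, tM = _as_twice(J), _as_twice(M)
    _check_jm(tj1, tm1)
    _check_jm(tj2, tm2)
    _check_jm(tJ, tM)
    return _cg_twice(tj1, tm1, tj2, tm2, tJ, tM)


def wigner_3j(j1: HalfIntLike, j2: HalfIntLike, j3: HalfIntLike,
              m1: HalfIntLike, m2: HalfIntLike, m3: HalfIntLike) -> SymbolValue:
    """Wigner 3-jm symbol; zero outside the selection rules."""
    tj1, tj2, tj3 = _as_twice(j1), _as_twice(j2), _as_twice(j3)
    tm1, tm2, tm3 = _as_twice(m1), _as_twice(m2), _as_twice(m3)
    if tm1 + tm2 + tm3 != 0:
        return SymbolValue.zero()
    if not triangle_ok(HalfInt(twice=tj1), HalfInt(twice=tj2), HalfInt(twice=tj3)):
        return SymbolValue.zero()
    cg = _cg_twice(tj1, tm1, tj2, tm2, tj3, -tm3)
    phase = -1 if ((tj1 - tj2 - tm3) // 2) % 2 else 1
    return cg * SymbolValue.make(phase, Fraction(1, tj3 + 1))


@lru_cache(maxsize=None)
def _wigner_6j_twice(tj1: int, tj2: int, tj3: int,
                     tj4: int, tj5: int, tj6: int) -> SymbolValue:
    triads = ((tj1, tj2, tj3), (tj1, tj5, tj6), (tj4, tj2, tj6), (tj4, tj5, tj3))
    for ta, tb, tc in triads:
        if not triangle_ok(HalfInt(twice=ta), HalfInt(twice=tb), HalfInt(twice=tc)):
            return SymbolValue.zero()
    pref = Fraction(1)
    for ta, tb, tc in triads:
        pref *= _triangle_factor(ta, tb, tc)
    ta1 = tj1 + tj2 + tj3
    ta2 = tj1 + tj5 + tj6
    ta3 = tj4 + tj2 + tj6
    ta4 = tj4 + tj5 + tj3
    tb1 = tj1 + tj2 + tj4 + tj5
    tb2 = tj2 + tj3 + tj5 + tj6
    tb3 = tj3 + tj1 + tj6 + tj4
    total = Fraction(0)
    for tt in range(max(ta1, ta2, ta3, ta4), min(tb1, tb2, tb3) + 1, 2):
        term = Fraction(
            _fact_half(tt + 2),
            _fact_half(tt - ta1) * _fact_half(tt - ta2) * _fact_half(tt - ta3)
            * _fact_half(tt - ta4) * _fact_half(tb1 - tt) * _fact_half(tb2 - tt)
            * _fact_half(tb3 - tt),
        )
        total += term if tt % 4 == 0 else -term
    return SymbolValue.make(total) * SymbolValue.make(1, pref)


def wigner_6j(j1: HalfIntLike, j2: HalfIntLike, j3: HalfIntLike,
              j4: HalfIntLike, j5: HalfIntLike, j6: HalfIntLike) -> SymbolValue:
    """Wigner 6j symbol {j1 j2 j3; j4 j5 j6}, exact (Racah single sum).

    Invariant under any permutation of its columns and under exchange of
    the upper and lower entries in any two columns; exact zero whenever
    one of the four triads (j1j2j3), (j1j5j6), (j4j2j6), (j4j5j3) violates
    the triangle rule.
    """
    return _wigner_6j_twice(_as_twice(j1), _as_twice(j2), _as_twice(j3),
                            _as_twice(j4), _as_twice(j5), _as_twice(j6))


def racah_w(a: HalfIntLike, b: HalfIntLike, c: HalfIntLike, d: HalfIntLike,
            e: HalfIntLike, f: HalfIntLike) -> SymbolValue:
    """Racah coefficient W(abcd; ef) = (-1)^(a+b+c+d) {a b e; d c f}.

    The phase exponent a+b+c+d is an integer whenever the triads of the
    underlying 6j symbol are valid; outside the triangle rules the value
    is exact zero (and the phase is irrelevant).
    """
    ta, tb, tc, td = _as_twice(a), _as_twice(b), _as_twice(c), _as_twice(d)
    six = _wigner_6j_twice(ta, tb, _as_twice(e), td, tc, _as_twice(f))
    if six.is_zero:
        return six
    texp = ta + tb + tc + td
    if texp % 2:
        raise RuntimeError("non-integer Racah phase for valid triads")
    return six if texp % 4 == 0 else -six


def weighted_w(a: HalfIntLike, b: HalfIntLike, c: HalfIntLike, d: HalfIntLike,
               e: HalfIntLike, f: HalfIntLike) -> SymbolValue:
    """Dimension-weighted Racah symbol W~(a,b,c,d; e,f).

    W~ = sqrt((2e+1)(2f+1)) * W(abcd; ef): the Racah coefficient with the
    square-root dimension factors of both intermediate momenta absorbed.
    With this normalization the elementary recoupling bracket

        <(j1 j2) J12, j3; J | j1, (j2 j3) J23; J> = W~(j1, j2, J, j3; J12, J23)

    carries no residual phase, so chain-of-spins recoupling coefficients
    are plain products of W~ symbols.  Real for all valid inputs and zero
    whenever the underlying W vanishes.
    """
    w = racah_w(a, b, c, d, e, f)
    if w.is_zero:
        return w
    dim = Fraction((_as_twice(e) + 1) * (_as_twice(f) + 1))
    return w * SymbolValue.make(1, dim)
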