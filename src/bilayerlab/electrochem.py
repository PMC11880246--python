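"""Equilibrium and reversal potentials, and permeability-ratio inversion.

This module implements the electrochemistry used to interpret bilayer
reversal potentials:

* the Nernst equation for a single ion species,
* the Goldman-Hodgkin-Katz (GHK) voltage equation for baths of monovalent
  ions (closed form),
* an extended GHK voltage equation that admits divalent cations.  Because
  a divalent species makes the equation implicit in the membrane potential
  (the potential appears inside the Boltzmann factor on both sides), it is
  solved numerically by bracketed bisection,
* closed-form inversions of both equations for a single unknown
  permeability, returning relative permeability ratios such as
  P_K+/P_Cl- or P_Ca2+/P_K+.

Conventions
-----------
Units are mV, mM and K throughout.  The "out" compartment is the *cis*
chamber of the bilayer rig (the side the protein is added to) and "in" is
*trans*; membrane potentials are cis minus trans.  Concentrations are used
as-is: no activity-coefficient or liquid-junction corrections are applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .exceptions import (
    AmbiguousRootError,
    DomainError,
    NoSolutionError,
    UnsupportedEquationError,
)

__all__ = [
    "FARADAY_C_PER_MOL",
    "GAS_CONSTANT_J_PER_MOL_K",
    "DEFAULT_TEMPERATURE_K",
    "rt_over_f_mV",
    "temperature_for_rt_over_f",
    "IonSpecies",
    "BathPair",
    "PermeabilityResult",
    "nernst_potential",
    "ghk_reversal_monovalent",
    "invert_monovalent_ratio",
    "ghk_reversal_extended",
    "invert_divalent_ratio",
]

FARADAY_C_PER_MOL = 96485.33212
GAS_CONSTANT_J_PER_MOL_K = 8.314462618
DEFAULT_TEMPERATURE_K = 298.15

#: Valences of the ions produced by the salt recipes this package understands.
ION_VALENCES: dict[str, int] = {
    "K+": +1,
    "Na+": +1,
    "Cs+": +1,
    "Li+": +1,
    "Ca2+": +2,
    "Mg2+": +2,
    "Ba2+": +2,
    "Cl-": -1,
}

#: Salt -> [(ion, stoichiometry), ...] expansion for bath recipes.
SALT_IONS: dict[str, list[tuple[str, int]]] = {
    "KCl": [("K+", 1), ("Cl-", 1)],
    "NaCl": [("Na+", 1), ("Cl-", 1)],
    "CsCl": [("Cs+", 1), ("Cl-", 1)],
    "LiCl": [("Li+", 1), ("Cl-", 1)],
    "CaCl2": [("Ca2+", 1), ("Cl-", 2)],
    "MgCl2": [("Mg2+", 1), ("Cl-", 2)],
    "BaCl2": [("Ba2+", 1), ("Cl-", 2)],
}


def rt_over_f_mV(temperature_K: float) -> float:
    """Thermal voltage RT/F in millivolts at the given absolute temperature."""
    if temperature_K <= 0:
        raise DomainError(f"temperature must be positive, got {temperature_K} K")
    return 1000.0 * GAS_CONSTANT_J_PER_MOL_K * temperature_K / FARADAY_C_PER_MOL


def temperature_for_rt_over_f(rt_over_f: float) -> float:
    """Absolute temperature (K) at which RT/F equals ``rt_over_f`` mV."""
    if rt_over_f <= 0:
        raise DomainError(f"RT/F must be positive, got {rt_over_f} mV")
    return rt_over_f * 1e-3 * FARADAY_C_PER_MOL / GAS_CONSTANT_J_PER_MOL_K


@dataclass(frozen=True)
class IonSpecies:
    """One permeant (or impermeant) ion species in a two-sided bath.

    Parameters
    ----------
    name : str
        Short label, e.g. ``"K+"`` or ``"Ca2+"``.
    valence : int
        Signed charge; the supported equations cover -1, +1 and +2.
    conc_out_mM, conc_in_mM : float
        Concentrations on the cis ("out") and trans ("in") sides, mM.
    permeability : float
        Relative permeability (dimensionless; one species serves as the
        reference with permeability 1).
    """

    name: str
    valence: int
    conc_out_mM: float
    conc_in_mM: float
    permeability: float = 0.0

    def __post_init__(self):
        if self.conc_out_mM < 0 or self.conc_in_mM < 0:
            raise DomainError(f"{self.name}: concentrations must be >= 0")
        if self.valence not in (-1, +1, +2):
            raise DomainError(
                f"{self.name}: valence {self.valence} is outside the supported "
                "set {-1, +1, +2}"
            )
        if self.permeability < 0:
            raise DomainError(f"{self.name}: permeability must be >= 0")

    def swapped(self) -> "IonSpecies":
        """The same species with out/in concentrations exchanged."""
        return replace(
            self, conc_out_mM=self.conc_in_mM, conc_in_mM=self.conc_out_mM
        )


@dataclass(frozen=True)
class BathPair:
    """The two bath solutions flanking the bilayer, plus the temperature.

    Build directly from :class:`IonSpecies`, or from salt recipes with
    :meth:`from_salts` (which guarantees electroneutrality per side).
    Either ``temperature_K`` or ``rt_over_f_mV`` may be given; the other is
    derived.  Supplying both requires them to be mutually consistent.
    """

    species: tuple[IonSpecies, ...]
    temperature_K: float = DEFAULT_TEMPERATURE_K
    rt_over_f_mV: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not self.species:
            raise DomainError("bath must contain at least one species")
        if self.temperature_K is None and self.rt_over_f_mV is None:
            object.__setattr__(self, "temperature_K", DEFAULT_TEMPERATURE_K)
        if self.temperature_K is None:
            object.__setattr__(
                self, "temperature_K", temperature_for_rt_over_f(self.rt_over_f_mV)
            )
        if self.temperature_K <= 0:
            raise DomainError("temperature_K must be positive")
        derived = rt_over_f_mV(self.temperature_K)
        if self.rt_over_f_mV is None:
            object.__setattr__(self, "rt_over_f_mV", derived)
        elif not math.isclose(self.rt_over_f_mV, derived, rel_tol=1e-9):
            raise DomainError(
                f"rt_over_f_mV={self.rt_over_f_mV} inconsistent with "
                f"temperature_K={self.temperature_K} (implies {derived:.6f} mV)"
            )

    @classmethod
    def from_salts(
        cls,
        cis: Mapping[str, float],
        trans: Mapping[str, float],
        permeabilities: Mapping[str, float] | None = None,
        temperature_K: float | None = None,
        rt_over_f: float | None = None,
    ) -> "BathPair":
        """Build a bath from salt recipes, e.g. ``cis={"KCl": 500}``.

        Salts dissociate completely with their stoichiometry (``CaCl2: 150``
        contributes Ca2+ 150 mM and Cl- 300 mM).  ``permeabilities`` maps ion
        names to relative permeabilities; unlisted ions get 0.  Buffers
        (HEPES etc.) are not ions here and are simply omitted from recipes.
        """
        permeabilities = dict(permeabilities or {})
        conc: dict[str, list[float]] = {}
        for side_idx, recipe in enumerate((cis, trans)):
            for salt, mM in recipe.items():
                if mM < 0:
                    raise DomainError(f"salt concentration must be >= 0: {salt}={mM}")
                if salt not in SALT_IONS:
                    raise DomainError(
                        f"unknown salt {salt!r}; known: {sorted(SALT_IONS)}"
                    )
                for ion, stoich in SALT_IONS[salt]:
                    conc.setdefault(ion, [0.0, 0.0])[side_idx] += stoich * mM
        unknown = set(permeabilities) - set(conc)
        if unknown:
            raise DomainError(f"permeabilities given for absent ions: {sorted(unknown)}")
        species = tuple(
            IonSpecies(
                name=ion,
                valence=ION_VALENCES[ion],
                conc_out_mM=c[0],
                conc_in_mM=c[1],
                permeability=permeabilities.get(ion, 0.0),
            )
            for ion, c in sorted(conc.items())
        )
        bath = cls(
            species=species,
            temperature_K=temperature_K,  # type: ignore[arg-type]
            rt_over_f_mV=rt_over_f,  # type: ignore[arg-type]
        )
        bath.check_electroneutrality()
        return bath

    def check_electroneutrality(self, rel_tol: float = 1e-6) -> None:
        """Raise if either side carries net charge beyond ``rel_tol`` of its
        total ionic strength."""
        for side in ("out", "in"):
            net = sum(s.valence * self._conc(s, side) for s in self.species)
            total = sum(abs(s.valence) * self._conc(s, side) for s in self.species)
            if total > 0 and abs(net) > rel_tol * total:
                raise DomainError(
                    f"{side} side is not electroneutral: net charge {net} mM"
                )

    @staticmethod
    def _conc(species: IonSpecies, side: str) -> float:
        return species.conc_out_mM if side == "out" else species.conc_in_mM

    def get(self, name: str) -> IonSpecies:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(f"no species named {name!r} in bath")

    def with_permeabilities(self, permeabilities: Mapping[str, float]) -> "BathPair":
        """A copy with the listed species' permeabilities replaced."""
        new = tuple(
            replace(s, permeability=permeabilities.get(s.name, s.permeability))
            for s in self.species
        )
        return replace(self, species=new)

    def swapped(self) -> "BathPair":
        """A copy with every species' out/in concentrations exchanged."""
        return replace(self, species=tuple(s.swapped() for s in self.species))

    @property
    def cations_monovalent(self) -> list[IonSpecies]:
        return [s for s in self.species if s.valence == +1]

    @property
    def cations_divalent(self) -> list[IonSpecies]:
        return [s for s in self.species if s.valence == +2]

    @property
    def anions(self) -> list[IonSpecies]:
        return [s for s in self.species if s.valence == -1]


@dataclass(frozen=True)
class PermeabilityResult:
    """A relative permeability ratio inferred from a reversal potential.

    ``ratio`` is P(numerator_species)/P(denominator_species).  The result
    records the reversal potential and thermal voltage used so that the
    forward GHK equation can be re-evaluated from it alone.
    """

    numerator_species: str
    denominator_species: str
    ratio: float
    e_rev_mV: float
    method: str  # "closed_form_inverse" | "bisection_forward"
    rt_over_f_mV: float

    def __str__(self) -> str:
        return (
            f"P_{self.numerator_species}/P_{self.denominator_species} = "
            f"{self.ratio:.4g} (E_rev = {self.e_rev_mV:.2f} mV, "
            f"RT/F = {self.rt_over_f_mV:.2f} mV, {self.method})"
        )


def nernst_potential(
    valence: int,
    conc_out_mM: float,
    conc_in_mM: float,
    rt_over_f: float | None = None,
    temperature_K: float | None = None,
) -> float:
    """Equilibrium (Nernst) potential of a single ion species, in mV.

    E = (RT/zF) ln(c_out / c_in).  Antisymmetric under exchanging the two
    sides.  ``rt_over_f`` (mV) takes precedence over ``temperature_K``;
    the default temperature is 298.15 K.
    """
    if conc_out_mM <= 0 or conc_in_mM <= 0:
        raise DomainError(
            "Nernst potential requires strictly positive concentrations, got "
            f"{conc_out_mM}:{conc_in_mM} mM"
        )
    if valence == 0:
        raise DomainError("Nernst potential is undefined for a neutral species")
    if rt_over_f is None:
        rt_over_f = rt_over_f_mV(
            DEFAULT_TEMPERATURE_K if temperature_K is None else temperature_K
        )
    return (rt_over_f / valence) * math.log(conc_out_mM / conc_in_mM)


def _monovalent_sums(bath: BathPair) -> tuple[float, float]:
    """Numerator and denominator of the monovalent GHK log argument."""
    num = den = 0.0
    for s in bath.species:
        if s.permeability == 0.0:
            continue
        if s.valence == +1:
            num += s.permeability * s.conc_out_mM
            den += s.permeability * s.conc_in_mM
        else:  # anion: sides exchange
            num += s.permeability * s.conc_in_mM
            den += s.permeability * s.conc_out_mM
    return num, den


def ghk_reversal_monovalent(bath: BathPair) -> float:
    """Reversal potential (mV) from the GHK voltage equation, monovalent ions.

    E_rev = (RT/F) ln[(sum_cat P c_out + sum_an P c_in) /
    (sum_cat P c_in + sum_an P c_out)].  With a single permeant species this
    reduces exactly to its Nernst potential.

    Raises
    ------
    UnsupportedEquationError
        If a species with \\|valence\\| != 1 is present (use
        :func:`ghk_reversal_extended` for divalent cations).
    DomainError
        If no species has positive permeability, or a permeant species has a
        zero concentration that empties one side of the equation.
    """
    for s in bath.species:
        if abs(s.valence) != 1:
            raise UnsupportedEquationError(
                f"species {s.name} (z={s.valence:+d}) is not monovalent; use "
                "ghk_reversal_extended for divalent cations"
            )
    num, den = _monovalent_sums(bath)
    if num == 0.0 and den == 0.0:
        raise DomainError("all permeabilities are zero; reversal potential undefined")
    if num <= 0.0 or den <= 0.0:
        raise DomainError(
            "GHK log argument is not positive; a permeant species has zero "
            "concentration on one side"
        )
    return bath.rt_over_f_mV * math.log(num / den)


def invert_monovalent_ratio(
    e_rev_mV: float,
    bath: BathPair,
    reference_cation: str = "K+",
    target_anion: str = "Cl-",
) -> PermeabilityResult:
    """Solve the monovalent GHK equation for the anion's relative permeability.

    With the reference cation's permeability fixed at 1 and
    u = exp(E_rev F / RT), the equation is linear in the unknown:

        P_an/P_cat = (c_cat_out - u c_cat_in) / (u c_an_out - c_an_in)

    The returned :class:`PermeabilityResult` reports the conventional
    cation-over-anion ratio (e.g. P_K+/P_Cl-), the reciprocal of the solved
    quantity.

    Raises :class:`NoSolutionError` if ``e_rev_mV`` lies outside the interval
    attainable between the pure-cation and pure-anion limits (the computed
    ratio would be negative there).
    """
    cat = bath.get(reference_cation)
    an = bath.get(target_anion)
    if cat.valence != +1 or an.valence != -1:
        raise UnsupportedEquationError(
            "reference must be a monovalent cation and target a monovalent anion"
        )
    for s in bath.species:
        if s.name not in (cat.name, an.name) and s.permeability != 0.0:
            raise UnsupportedEquationError(
                f"species {s.name} has nonzero permeability; the closed-form "
                "inversion supports exactly one cation and one anion"
            )
    rtf = bath.rt_over_f_mV
    u = math.exp(e_rev_mV / rtf)
    num = cat.conc_out_mM - u * cat.conc_in_mM
    den = u * an.conc_out_mM - an.conc_in_mM
    # Attainable band: E_rev approaches the cation Nernst potential as
    # P_an -> 0 and the anion equilibrium potential as P_an -> inf.
    e_cat = nernst_potential(+1, cat.conc_out_mM, cat.conc_in_mM, rt_over_f=rtf)
    e_an = nernst_potential(-1, an.conc_out_mM, an.conc_in_mM, rt_over_f=rtf)
    lo, hi = sorted((e_cat, e_an))
    if not (lo <= e_rev_mV <= hi):
        raise NoSolutionError(
            f"E_rev = {e_rev_mV} mV is outside the attainable interval "
            f"[{lo:.2f}, {hi:.2f}] mV for this bath"
        )
    if den == 0.0:
        raise NoSolutionError("anion permeability unidentifiable at this E_rev")
    # clamp numerical noise at the pure-cation limit (num analytically 0)
    if abs(num) <= 1e-12 * (cat.conc_out_mM + u * cat.conc_in_mM):
        num = 0.0
    p_an = num / den
    if p_an < 0:
        raise NoSolutionError(
            f"computed P_{an.name}/P_{cat.name} = {p_an:.4g} is negative"
        )
    if p_an == 0.0:
        ratio = math.inf
    else:
        ratio = 1.0 / p_an
    result = PermeabilityResult(
        numerator_species=cat.name,
        denominator_species=an.name,
        ratio=ratio,
        e_rev_mV=e_rev_mV,
        method="closed_form_inverse",
        rt_over_f_mV=rtf,
    )
    _check_forward_consistency_monovalent(result, bath)
    return result


def _check_forward_consistency_monovalent(
    result: PermeabilityResult, bath: BathPair
) -> None:
    perms = {result.numerator_species: 1.0}
    if math.isfinite(result.ratio):
        perms[result.denominator_species] = 1.0 / result.ratio
    else:
        perms[result.denominator_species] = 0.0
    check = ghk_reversal_monovalent(bath.with_permeabilities(perms))
    if abs(check - result.e_rev_mV) > 1e-6:
        raise NoSolutionError(
            f"forward consistency check failed: GHK({result.ratio}) = "
            f"{check:.9f} mV != {result.e_rev_mV} mV"
        )


def _extended_log_ratio(bath: BathPair, u: float, include_anions: bool) -> float:
    """log(N(u)/D(u)) of the divalent-capable GHK equation.

    N = sum_cat+ P c_out (1+u) + sum_cat2+ 4 P c_out [+ sum_an P c_in (1+u)]
    D = sum_cat+ P c_in (1+u) + sum_cat2+ 4 P c_in u [+ sum_an P c_out (1+u)]
    """
    n = d = 0.0
    for s in bath.species:
        if s.permeability == 0.0:
            continue
        if s.valence == +1:
            n += s.permeability * s.conc_out_mM * (1.0 + u)
            d += s.permeability * s.conc_in_mM * (1.0 + u)
        elif s.valence == +2:
            n += 4.0 * s.permeability * s.conc_out_mM
            d += 4.0 * s.permeability * s.conc_in_mM * u
        elif include_anions:
            n += s.permeability * s.conc_in_mM * (1.0 + u)
            d += s.permeability * s.conc_out_mM * (1.0 + u)
    if n <= 0.0 or d <= 0.0:
        raise DomainError(
            "extended GHK log argument is not positive; check permeabilities "
            "and concentrations"
        )
    return math.log(n / d)


def ghk_reversal_extended(
    bath: BathPair,
    include_anions: bool = False,
    bracket_mV: tuple[float, float] = (-500.0, 500.0),
    tol_mV: float = 1e-9,
) -> float:
    """Reversal potential (mV) from the GHK equation with divalent cations.

    The divalent terms make the equation implicit: with u = exp(E F/RT),

        E = (RT/F) ln[ (sum P_+ c_out (1+u) + sum 4 P_2+ c_out) /
                       (sum P_+ c_in (1+u) + sum 4 P_2+ c_in u) ]

    Anion terms are excluded by default; ``include_anions=True`` adds them in
    the standard GHK positions (inner concentration in the numerator), with
    the same (1+u) weighting as the monovalent cations so that the equation
    still collapses to the monovalent form when no divalent ion is present.

    The root is found by scanning ``bracket_mV`` for sign changes of
    E - (RT/F) ln(N/D) and bisecting to ``tol_mV``.  Zero sign changes raise
    :class:`NoSolutionError`; more than one raise :class:`AmbiguousRootError`
    carrying all bracketing intervals.

    When every divalent concentration is zero the result equals
    :func:`ghk_reversal_monovalent` on the corresponding bath exactly.
    """
    for s in bath.species:
        if s.valence == +2 and s.permeability > 0:
            break
    else:
        # No permeant divalent: fall through to the closed form for an exact
        # reduction (anions obey include_anions).
        perms = {
            s.name: (s.permeability if s.valence == +1 or include_anions else 0.0)
            for s in bath.species
        }
        mono = BathPair(
            species=tuple(
                replace(s, permeability=perms[s.name])
                for s in bath.species
                if abs(s.valence) == 1
            ),
            temperature_K=bath.temperature_K,
            rt_over_f_mV=bath.rt_over_f_mV,
        )
        return ghk_reversal_monovalent(mono)

    rtf = bath.rt_over_f_mV

    def residual(e_mV: float) -> float:
        u = math.exp(e_mV / rtf)
        return e_mV - rtf * _extended_log_ratio(bath, u, include_anions)

    # Exact reduction when the permeant divalents all have zero concentration
    # on both sides: the (1+u) factors cancel and the closed form applies.
    if all(
        s.conc_out_mM == 0.0 and s.conc_in_mM == 0.0
        for s in bath.cations_divalent
        if s.permeability > 0
    ):
        perms = {
            s.name: (
                s.permeability
                if s.valence == +1 or (include_anions and s.valence == -1)
                else 0.0
            )
            for s in bath.species
        }
        mono = BathPair(
            species=tuple(
                replace(s, permeability=perms[s.name])
                for s in bath.species
                if abs(s.valence) == 1
            ),
            temperature_K=bath.temperature_K,
            rt_over_f_mV=bath.rt_over_f_mV,
        )
        return ghk_reversal_monovalent(mono)

    lo, hi = bracket_mV
    n_scan = 1000
    step = (hi - lo) / n_scan
    grid = [lo + i * step for i in range(n_scan + 1)]
    vals = [residual(g) for g in grid]
    exact = [g for g, v in zip(grid, vals) if v == 0.0]
    brackets = [
        (grid[i], grid[i + 1])
        for i in range(n_scan)
        if vals[i] != 0.0 and vals[i + 1] != 0.0 and (vals[i] < 0) != (vals[i + 1] < 0)
    ]
    n_roots = len(exact) + len(brackets)
    if n_roots == 0:
        raise NoSolutionError(
            f"no sign change of the GHK residual in [{lo}, {hi}] mV"
        )
    if n_roots > 1:
        raise AmbiguousRootError(
            f"{n_roots} candidate roots found in [{lo}, {hi}] mV",
            brackets + [(g, g) for g in exact],
        )
    if exact:
        return exact[0]
    a, b = brackets[0]
    fa = residual(a)
    while (b - a) > max(tol_mV, 1e-13):
        m = 0.5 * (a + b)
        fm = residual(m)
        if fm == 0.0:
            return m
        if (fm < 0) == (fa < 0):
            a, fa = m, fm
        else:
            b = m
    return 0.5 * (a + b)


def invert_divalent_ratio(
    e_rev_mV: float,
    bath: BathPair,
    reference_cation: str = "K+",
    divalent_cation: str | None = None,
    include_anions: bool = False,
) -> PermeabilityResult:
    """Solve the extended GHK equation for the divalent cation's permeability.

    All monovalent (and, if enabled, anion) permeabilities are taken from the
    bath as known; the single divalent cation's permeability is the unknown.
    With u = exp(E_rev F/RT) fixed by the measurement, the equation is linear
    in P_div:

        P_div = [u D_mono(u) - N_mono(u)] / [4 (c_div_out - u^2 c_div_in)]

    where N_mono/D_mono collect the known terms.  The result reports
    P_div/P_reference and must agree with the forward solver to 1e-6 mV.

    Raises :class:`NoSolutionError` when the linear coefficient vanishes
    (the ratio is unidentifiable at this reversal potential) or when the
    solution is negative.
    """
    divalents = [s for s in bath.cations_divalent]
    if divalent_cation is None:
        if len(divalents) != 1:
            raise UnsupportedEquationError(
                "bath must contain exactly one divalent cation, or name it "
                "explicitly"
            )
        div = divalents[0]
    else:
        div = bath.get(divalent_cation)
        if div.valence != +2:
            raise UnsupportedEquationError(f"{divalent_cation} is not divalent")
    ref = bath.get(reference_cation)
    if ref.valence != +1 or ref.permeability <= 0:
        raise UnsupportedEquationError(
            "reference cation must be monovalent with positive permeability"
        )
    rtf = bath.rt_over_f_mV
    u = math.exp(e_rev_mV / rtf)
    n_mono = d_mono = 0.0
    for s in bath.species:
        if s.valence == +2 or s.permeability == 0.0:
            continue
        if s.valence == +1:
            n_mono += s.permeability * s.conc_out_mM * (1.0 + u)
            d_mono += s.permeability * s.conc_in_mM * (1.0 + u)
        elif include_anions:
            n_mono += s.permeability * s.conc_in_mM * (1.0 + u)
            d_mono += s.permeability * s.conc_out_mM * (1.0 + u)
    coeff = 4.0 * (div.conc_out_mM - u * u * div.conc_in_mM)
    rhs = u * d_mono - n_mono
    # clamp numerical noise at the monovalent-only limit (rhs analytically 0)
    if abs(rhs) <= 1e-12 * (u * d_mono + n_mono):
        rhs = 0.0
    if abs(coeff) < 1e-12 * max(1.0, 4.0 * (div.conc_out_mM + div.conc_in_mM)):
        raise NoSolutionError(
            f"P_{div.name} is unidentifiable at E_rev = {e_rev_mV} mV "
            "(linear coefficient vanishes)"
        )
    p_div = rhs / coeff
    if p_div < 0:
        raise NoSolutionError(
            f"computed P_{div.name} = {p_div:.4g} is negative; E_rev "
            "inconsistent with this bath"
        )
    ratio = p_div / ref.permeability
    result = PermeabilityResult(
        numerator_species=div.name,
        denominator_species=ref.name,
        ratio=ratio,
        e_rev_mV=e_rev_mV,
        method="closed_form_inverse",
        rt_over_f_mV=rtf,
    )
    if p_div > 0:
        check_bath = bath.with_permeabilities({div.name: p_div})
        check = ghk_reversal_extended(check_bath, include_anions=include_anions)
        if abs(check - e_rev_mV) > 1e-6:
            raise NoSolutionError(
                f"forward consistency check failed: {check:.9f} mV != {e_rev_mV} mV"
            )
    return result
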