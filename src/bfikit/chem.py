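"""Accurate-mass arithmetic and adduct/isotopologue annotation.

Flow-infusion electrospray fingerprinting reports each metabolite signal as an
accurate m/z with no chromatographic dimension, so annotation reduces to
matching observed m/z values against the theoretical ionization products
(adducts and single heavy-isotope isotopologues) of candidate neutral
molecules, within a ppm tolerance.  Monoisotopic and isotope masses, and the
electron mass, come from the NIST table shipped with pyteomics; the electron
mass is included because at Orbitrap resolution its omission alone costs
~2.7 ppm at m/z 200.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from pyteomics import mass as _ptmass

ELECTRON_MASS: float = _ptmass.nist_mass["e*"][0][0]

#: heavy-isotope substitutions in scope: label -> (element, light A, heavy A)
ISOTOPE_SUBSTITUTIONS: dict[str, tuple[str, int, int]] = {
    "13C": ("C", 12, 13),
    "34S": ("S", 32, 34),
    "41K": ("K", 39, 41),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def element_monoisotopic_mass(symbol: str) -> float:
    """Mass of the principal (most abundant) isotope of an element, in Da."""
    try:
        return _ptmass.nist_mass[symbol][0][0]
    except KeyError:
        raise ValueError(f"unknown element symbol: {symbol!r}") from None


def isotope_mass_shift(substitution: str) -> float:
    """m(heavy) - m(light) for a supported single-isotope substitution."""
    try:
        element, light, heavy = ISOTOPE_SUBSTITUTIONS[substitution]
    except KeyError:
        raise ValueError(
            f"unsupported isotope substitution: {substitution!r} "
            f"(supported: {sorted(ISOTOPE_SUBSTITUTIONS)})"
        ) from None
    table = _ptmass.nist_mass[element]
    return table[heavy][0] - table[light][0]


@dataclass(frozen=True)
class ChemicalFormula:
    """Elemental composition of a neutral molecule (or ion skeleton).

    Counts are non-negative; the empty formula (mass 0) is allowed so that
    ionization rules with no gains or no losses are expressible.
    """

    element_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for symbol, count in self.element_counts.items():
            if symbol not in _ptmass.nist_mass:
                raise ValueError(f"unknown element symbol: {symbol!r}")
            if not isinstance(count, int) or count < 0:
                raise ValueError(
                    f"element count must be a non-negative integer: {symbol}={count!r}"
                )
            if count > 0:
                clean[symbol] = count
        object.__setattr__(self, "element_counts", clean)

    @classmethod
    def parse(cls, text: str) -> "ChemicalFormula":
        """Parse Hill-notation text such as ``"C6H6O6S"``."""
        text = text.strip()
        if not text:
            return cls({})
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            if not match.group(0):
                break
            symbol = match.group(1)
            n = int(match.group(2)) if match.group(2) else 1
            counts[symbol] = counts.get(symbol, 0) + n
            pos = match.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        return cls(counts)

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        counts = dict(self.element_counts)
        for sym, n in other.element_counts.items():
            counts[sym] = counts.get(sym, 0) + n
        return ChemicalFormula(counts)

    def __sub__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        counts = dict(self.element_counts)
        for sym, n in other.element_counts.items():
            new = counts.get(sym, 0) - n
            if new < 0:
                raise ValueError(
                    f"cannot remove {n} {sym} from {self.hill()!r}: only "
                    f"{counts.get(sym, 0)} present"
                )
            counts[sym] = new
        return ChemicalFormula(counts)

    def count(self, symbol: str) -> int:
        return self.element_counts.get(symbol, 0)

    def hill(self) -> str:
        """Hill-notation string (C first, H second, rest alphabetical)."""
        syms = sorted(self.element_counts)
        ordered = [s for s in ("C", "H") if s in self.element_counts]
        ordered += [s for s in syms if s not in ("C", "H")]
        return "".join(
            f"{s}{self.element_counts[s] if self.element_counts[s] != 1 else ''}"
            for s in ordered
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill() or "(empty)"


def monoisotopic_mass(formula: ChemicalFormula) -> float:
    """Monoisotopic mass in Da: sum of principal-isotope masses."""
    return sum(
        n * element_monoisotopic_mass(sym)
        for sym, n in formula.element_counts.items()
    )


@dataclass(frozen=True)
class IonizationRule:
    """One adduct/loss transformation producing a singly charged ion.

    ``atom_gains``/``atom_losses`` describe the atoms added to / removed from
    the neutral molecule M; ``isotope_substitution`` optionally replaces one
    atom of the ion by its heavy stable isotope (13C, 34S or 41K).
    """

    label: str
    atom_gains: ChemicalFormula = field(default_factory=ChemicalFormula)
    atom_losses: ChemicalFormula = field(default_factory=ChemicalFormula)
    charge: int = -1
    isotope_substitution: Optional[str] = None

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError(f"rule {self.label!r}: charge must be non-zero")
        if abs(self.charge) != 1:
            raise ValueError(
                f"rule {self.label!r}: only singly charged ions are in scope"
            )
        if (
            self.isotope_substitution is not None
            and self.isotope_substitution not in ISOTOPE_SUBSTITUTIONS
        ):
            raise ValueError(
                f"rule {self.label!r}: unsupported isotope substitution "
                f"{self.isotope_substitution!r}"
            )

    @property
    def polarity(self) -> str:
        return "pos" if self.charge > 0 else "neg"

    def ion_composition(self, formula: ChemicalFormula) -> ChemicalFormula:
        """Full elemental composition of the ion (gains applied, losses removed)."""
        try:
            return (formula + self.atom_gains) - self.atom_losses
        except ValueError as exc:
            raise ValueError(
                f"rule {self.label!r} not applicable to {formula.hill()!r}: {exc}"
            ) from None

    def applicable(self, formula: ChemicalFormula) -> bool:
        try:
            ion = self.ion_composition(formula)
        except ValueError:
            return False
        if self.isotope_substitution is not None:
            element = ISOTOPE_SUBSTITUTIONS[self.isotope_substitution][0]
            return ion.count(element) >= 1
        return True


def ion_mz(formula: ChemicalFormula, rule: IonizationRule) -> float:
    """Theoretical m/z of the ionization product of ``formula`` under ``rule``.

    m/z = (monoisotopic mass of ion composition + isotope shift
           - charge * electron mass) / |charge|
    """
    ion = rule.ion_composition(formula)
    shift = 0.0
    if rule.isotope_substitution is not None:
        element = ISOTOPE_SUBSTITUTIONS[rule.isotope_substitution][0]
        if ion.count(element) < 1:
            raise ValueError(
                f"isotope substitution {rule.isotope_substitution} of rule "
                f"{rule.label!r} not applicable: ion {ion.hill()!r} contains no "
                f"{element}"
            )
        shift = isotope_mass_shift(rule.isotope_substitution)
    m = monoisotopic_mass(ion) + shift - rule.charge * ELECTRON_MASS
    return m / abs(rule.charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical


def assign_msi_level(
    *,
    standard_mass_match: bool = False,
    standard_rt_match: bool = False,
    msn_match: bool = False,
    literature_spectral_match: bool = False,
    class_only: bool = False,
) -> int:
    """Metabolomics Standards Initiative identification level.

    Level 1 requires a full match against an authentic standard (accurate
    mass, retention time and MSn); level 2 a putative match to literature or
    spectral-library data; anything else with at least one evidence flag is
    level 3 (compound class only).
    """
    flags = (
        standard_mass_match,
        standard_rt_match,
        msn_match,
        literature_spectral_match,
        class_only,
    )
    if not any(flags):
        raise ValueError("at least one evidence flag must be set")
    if standard_mass_match and standard_rt_match and msn_match:
        return 1
    if literature_spectral_match:
        return 2
    return 3


@dataclass(frozen=True)
class IonAnnotation:
    """A scored match of an observed m/z to one compound's ionization product."""

    compound_name: str
    formula: ChemicalFormula
    rule: IonizationRule
    theoretical_mz: float
    observed_mz: float
    ppm_error: float
    msi_level: int

    def __post_init__(self) -> None:
        if self.msi_level not in (1, 2, 3):
            raise ValueError(f"msi_level must be 1, 2 or 3, got {self.msi_level}")


def _rule(label: str, gains: str = "", losses: str = "", charge: int = -1,
          isotope: Optional[str] = None) -> IonizationRule:
    return IonizationRule(
        label=label,
        atom_gains=ChemicalFormula.parse(gains),
        atom_losses=ChemicalFormula.parse(losses),
        charge=charge,
        isotope_substitution=isotope,
    )


# Default rule set: the ionization-product labels observed for the packaged
# biomarker panel, split by polarity.  "gluc" denotes in-source loss of the
# dehydrated glucuronyl moiety C6H8O6 (176.03209 Da).
DEFAULT_RULES: tuple[IonizationRule, ...] = (
    # negative mode
    _rule("[M-H]1-", losses="H", charge=-1),
    _rule("[M-H]1-13C", losses="H", charge=-1, isotope="13C"),
    _rule("[M-H]1-34S", losses="H", charge=-1, isotope="34S"),
    _rule("[M-H-gluc]1-", losses="HC6H8O6", charge=-1),
    _rule("[M-H-gluc]1-13C", losses="HC6H8O6", charge=-1, isotope="13C"),
    _rule("[M-K]1-", losses="K", charge=-1),
    _rule("[M-K]1-13C", losses="K", charge=-1, isotope="13C"),
    _rule("[M-K]1-34S", losses="K", charge=-1, isotope="34S"),
    # positive mode
    _rule("[M+H]1+", gains="H", charge=1),
    _rule("[M+H]1+13C", gains="H", charge=1, isotope="13C"),
    _rule("[M+Na]1+", gains="Na", charge=1),
    _rule("[M+Na]1+13C", gains="Na", charge=1, isotope="13C"),
    _rule("[M+K]1+", gains="K", charge=1),
    _rule("[M+K]1+13C", gains="K", charge=1, isotope="13C"),
    _rule("[M+K]1+41K", gains="K", charge=1, isotope="41K"),
    _rule("[M+2Na-H]1+", gains="Na2", losses="H", charge=1),
    _rule("[M+KNa-H]1+", gains="KNa", losses="H", charge=1),
)

RULES_BY_LABEL: dict[str, IonizationRule] = {r.label: r for r in DEFAULT_RULES}


def rules_for_polarity(
    polarity: str, rules: Sequence[IonizationRule] = DEFAULT_RULES
) -> list[IonizationRule]:
    if polarity not in ("pos", "neg"):
        raise ValueError(f"polarity must be 'pos' or 'neg', got {polarity!r}")
    return [r for r in rules if r.polarity == polarity]


def annotate_mz(
    observed: float,
    polarity: str,
    db: Iterable[tuple[str, ChemicalFormula]],
    rules: Sequence[IonizationRule] = DEFAULT_RULES,
    tol_ppm: float = 5.0,
    msi_levels: Optional[Mapping[str, int]] = None,
) -> list[IonAnnotation]:
    """All (compound, rule) ion products within ``tol_ppm`` of ``observed``.

    Results are sorted by absolute ppm error, ties broken lexicographically by
    (compound name, rule label) so output is deterministic.  ``msi_levels``
    optionally maps compound name to an identification level (default 3,
    putative class-level annotation by accurate mass alone).
    """
    if tol_ppm <= 0:
        raise ValueError(f"tol_ppm must be positive, got {tol_ppm}")
    polar_rules = rules_for_polarity(polarity, rules)
    out: list[IonAnnotation] = []
    for row in db:
        try:
            name, formula = row
        except (TypeError, ValueError):
            raise ValueError(f"malformed database row: {row!r}") from None
        if not isinstance(formula, ChemicalFormula):
            raise ValueError(f"malformed database row for {name!r}: {formula!r}")
        for rule in polar_rules:
            if not rule.applicable(formula):
                continue
            theo = ion_mz(formula, rule)
            err = ppm_error(observed, theo)
            if abs(err) <= tol_ppm:
                out.append(
                    IonAnnotation(
                        compound_name=name,
                        formula=formula,
                        rule=rule,
                        theoretical_mz=theo,
                        observed_mz=observed,
                        ppm_error=err,
                        msi_level=(msi_levels or {}).get(name, 3),
                    )
                )
    out.sort(key=lambda a: (abs(a.ppm_error), a.compound_name, a.rule.label))
    return out
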