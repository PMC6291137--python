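"""Monoisotopic mass arithmetic for LDI-MSI annotation and calibration.

Elemental formula parsing, neutral monoisotopic masses, adduct ion m/z
(with the electron-mass correction used for singly/multiply charged
cations), gold-cluster and alkali-chloride calibration reference series,
and ppm mass errors.

Two mass conventions coexist deliberately:

* calibration references (``[Au_n]+``, ``[KNaCl]+``, ``[K2Cl]+``) are
  conventionally quoted as *neutral atomic sums* — no electron
  subtraction — which is how TOF lock-mass tables for sputtered metal
  clusters are printed;
* annotation masses for ``[M+X]+`` adduct ions subtract one electron
  mass per charge (``ion_minus_electron``).

Both are available through the ``electron_correction`` flag of
:func:`ion_mz` and the ``mass_convention`` field of
:class:`ReferencePeak`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ELECTRON_MASS",
    "MONOISOTOPIC_MASS",
    "ElementalComposition",
    "AdductSpec",
    "ReferencePeak",
    "STANDARD_ADDUCTS",
    "parse_formula",
    "parse_adduct",
    "monoisotopic_mass",
    "ion_mz",
    "gold_cluster_series",
    "salt_cluster_references",
    "default_reference_set",
    "ppm_error",
]

#: Rest mass of the electron in Da (CODATA 2018).
ELECTRON_MASS = 0.000548579909

#: Monoisotopic masses of the most abundant stable isotope, in Da.
#: Values from the AME2020 atomic mass evaluation / NIST atomic weights
#: compilation, truncated to 8 decimals (sub-ppb for all uses here).
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "H": 1.00782503,
    "B": 11.00930536,
    "C": 12.0,
    "N": 14.00307401,
    "O": 15.99491462,
    "F": 18.99840316,
    "Na": 22.98976928,
    "Mg": 23.98504170,
    "Si": 27.97692653,
    "P": 30.97376200,
    "S": 31.97207117,
    "Cl": 34.96885268,
    "K": 38.96370649,
    "Ca": 39.96259086,
    "Fe": 55.93493633,
    "Cu": 62.92959772,
    "Zn": 63.92914201,
    "Se": 79.91652176,
    "Br": 78.91833760,
    "Ag": 106.90509160,
    "I": 126.90447190,
    "Au": 196.96656879,
}


class FormulaError(ValueError):
    """Raised for unparseable or chemically invalid formula strings."""


@dataclass(frozen=True)
class ElementalComposition:
    """An elemental composition: element symbol -> nonnegative count.

    Immutable and hashable; supports ``+`` and integer ``*`` so adduct
    arithmetic reads naturally (``M + Na``).
    """

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        seen = set()
        total = 0
        for el, n in self.counts:
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
            if el in seen:
                raise FormulaError(f"duplicate element symbol: {el}")
            seen.add(el)
            total += n
        if total == 0:
            raise FormulaError("empty composition (all counts zero)")

    @classmethod
    def from_dict(cls, d: Mapping[str, int]) -> "ElementalComposition":
        items = tuple(sorted((el, int(n)) for el, n in d.items() if n))
        return cls(items)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        d = self.as_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) + n
        return ElementalComposition.from_dict(d)

    def __mul__(self, k: int) -> "ElementalComposition":
        if not isinstance(k, int) or k < 1:
            raise FormulaError(f"multiplier must be a positive integer, got {k!r}")
        return ElementalComposition.from_dict({el: n * k for el, n in self.counts})

    __rmul__ = __mul__

    def hill_formula(self) -> str:
        """Canonical Hill-order serialization (C, H, then alphabetical)."""
        d = self.as_dict()
        parts = []
        order = [el for el in ("C", "H") if el in d]
        order += sorted(el for el in d if el not in ("C", "H"))
        for el in order:
            n = d[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill_formula()


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)|(.)")


def parse_formula(text: str) -> ElementalComposition:
    """Parse an elemental formula such as ``"C6H13N3O3"`` or ``"(CH2)3O"``.

    Hill-style element tokens with optional integer multipliers and
    optional parenthesised groups. Unknown element symbols and garbled
    input raise :class:`FormulaError` naming the offending token.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    stack: list[dict[str, int]] = [{}]
    for m in _TOKEN.finditer(text):
        el, n, lpar, rpar, rmul, bad = m.groups()
        if bad is not None:
            raise FormulaError(f"unexpected character {bad!r} in formula {text!r}")
        if lpar:
            stack.append({})
        elif rpar:
            if len(stack) < 2:
                raise FormulaError(f"unbalanced ')' in formula {text!r}")
            grp = stack.pop()
            k = int(rmul) if rmul else 1
            for e, c in grp.items():
                stack[-1][e] = stack[-1].get(e, 0) + c * k
        else:
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol {el!r} in formula {text!r}")
            stack[-1][el] = stack[-1].get(el, 0) + (int(n) if n else 1)
    if len(stack) != 1:
        raise FormulaError(f"unbalanced '(' in formula {text!r}")
    if not stack[0]:
        raise FormulaError(f"no elements parsed from {text!r}")
    return ElementalComposition.from_dict(stack[0])


def monoisotopic_mass(comp: ElementalComposition | str) -> float:
    """Neutral monoisotopic mass in Da (sum of per-element masses)."""
    if isinstance(comp, str):
        comp = parse_formula(comp)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in comp.counts)


# -- adducts -----------------------------------------------------------

_CATIONIZING = {"H", "Na", "K", "NH4"}


@dataclass(frozen=True)
class AdductSpec:
    """A cationizing adduct: what is added to M, and the resulting charge.

    The charge defaults to the number of cationizing units in the label
    (``"+H+NH4"`` -> z=2); pass ``charge`` to override.
    """

    label: str
    added: ElementalComposition
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"adduct charge must be >= 1, got {self.charge}")


def parse_adduct(label: str, charge: int | None = None) -> AdductSpec:
    """Build an :class:`AdductSpec` from a label like ``"+Na"`` or ``"+H+NH4"``."""
    units = [u for u in label.replace(" ", "").split("+") if u]
    if not units:
        raise ValueError(f"no cationizing units in adduct label {label!r}")
    comp: dict[str, int] = {}
    for u in units:
        if u not in _CATIONIZING:
            raise ValueError(
                f"unsupported cationizing unit {u!r} (expected one of {sorted(_CATIONIZING)})"
            )
        for el, n in parse_formula(u).counts:
            comp[el] = comp.get(el, 0) + n
    z = len(units) if charge is None else charge
    canon = "+" + "+".join(units)
    return AdductSpec(canon, ElementalComposition.from_dict(comp), z)


#: The positive-mode adduct set used for metabolite annotation by default.
STANDARD_ADDUCTS: tuple[AdductSpec, ...] = (
    parse_adduct("+H"),
    parse_adduct("+Na"),
    parse_adduct("+K"),
    parse_adduct("+NH4"),
)


def ion_mz(
    neutral: ElementalComposition | str,
    adduct: AdductSpec | str | None,
    electron_correction: bool = True,
) -> float:
    """m/z of the adduct ion ``[M + adduct]^z+``.

    ``(mass(M) + mass(adduct) - z*m_e) / z`` with the electron term
    dropped when ``electron_correction`` is off. ``adduct=None`` means
    a bare ``[M]+`` (z=1, nothing added).
    """
    if isinstance(adduct, str):
        adduct = parse_adduct(adduct)
    if adduct is None:
        z, added = 1, 0.0
    else:
        z, added = adduct.charge, monoisotopic_mass(adduct.added)
    if z < 1:
        raise ValueError("adduct charge must be >= 1")
    m = monoisotopic_mass(neutral) + added
    if electron_correction:
        m -= z * ELECTRON_MASS
    return m / z


# -- calibration references --------------------------------------------


@dataclass(frozen=True)
class ReferencePeak:
    """A lock-mass reference peak for internal calibration."""

    label: str
    mz: float
    mass_convention: str = "neutral_sum"

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"reference m/z must be positive, got {self.mz}")
        if self.mass_convention not in ("neutral_sum", "ion_minus_electron"):
            raise ValueError(f"unknown mass convention {self.mass_convention!r}")


def gold_cluster_series(n_max: int = 5) -> list[ReferencePeak]:
    """``[Au_n]+`` cluster references, n = 1..n_max, as neutral sums.

    Sputtered gold produces cluster ions at integer multiples of the Au
    monoisotopic mass in every pixel; these are the primary internal
    calibration references of the method.
    """
    if not (1 <= n_max <= 10):
        raise ValueError(f"n_max must be in 1..10, got {n_max}")
    au = MONOISOTOPIC_MASS["Au"]
    return [ReferencePeak(f"Au{n}", n * au, "neutral_sum") for n in range(1, n_max + 1)]


def salt_cluster_references() -> list[ReferencePeak]:
    """``[KNaCl]+`` and ``[K2Cl]+`` low-mass references (neutral sums).

    These anchor the calibration fit below the first gold cluster.
    """
    return [
        ReferencePeak("KNaCl", monoisotopic_mass("KNaCl"), "neutral_sum"),
        ReferencePeak("K2Cl", monoisotopic_mass("K2Cl"), "neutral_sum"),
    ]


def default_reference_set() -> list[ReferencePeak]:
    """The seven standard references: two salt clusters + Au1..Au5."""
    return salt_cluster_references() + gold_cluster_series(5)


def ppm_error(observed: float, theoretical: float, flip_sign: bool = False) -> float:
    """Signed relative mass error in parts per million.

    Default convention: ``(theoretical - observed) / theoretical * 1e6``;
    ``flip_sign`` selects the opposite sign convention.
    """
    if observed <= 0 or theoretical <= 0:
        raise ValueError("masses must be positive")
    ppm = (theoretical - observed) / theoretical * 1e6
    return -ppm if flip_sign else ppm


def write_reference_table(refs: Iterable[ReferencePeak], path) -> None:
    """Serialize references as 3-column TSV (label, mz, convention)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("label\tmz\tmass_convention\n")
        for r in refs:
            fh.write(f"{r.label}\t{r.mz:.6f}\t{r.mass_convention}\n")


def read_reference_table(path) -> list[ReferencePeak]:
    """Read a 3-column reference TSV written by :func:`write_reference_table`."""
    refs = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split("\t")
        if header[:2] != ["label", "mz"]:
            raise ValueError(f"unexpected reference table header: {header}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            conv = parts[2] if len(parts) > 2 else "neutral_sum"
            refs.append(ReferencePeak(parts[0], float(parts[1]), conv))
    labels = [r.label for r in refs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate reference labels in table")
    return refs
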