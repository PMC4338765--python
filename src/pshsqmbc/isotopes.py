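"""Spin-1/2 isotope registry.

Gyromagnetic ratios are stored relative to 1H as the IUPAC recommended NMR
frequency ratios Xi (nu(X)/nu(1H) at constant field), signed according to the
sign of gamma.  The three heteronuclei used throughout (13C, 31P, 77Se) all
have positive gamma.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Isotope", "REGISTRY", "get_isotope", "GAMMA_1H_HZ_PER_G"]

#: gamma(1H)/2pi in Hz per gauss (42.577 MHz/T), used by the slice-selection
#: sensitivity calculator.
GAMMA_1H_HZ_PER_G = 4257.74769


@dataclass(frozen=True)
class Isotope:
    """A spin-1/2 nuclide.

    Parameters
    ----------
    name : str
        Conventional label, mass number first (``"1H"``, ``"13C"`` ...).
    gamma_rel : float
        Gyromagnetic ratio relative to 1H (dimensionless, signed).
    """

    name: str
    gamma_rel: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


# IUPAC frequency ratios Xi/100 (Harris et al. recommendations), >=6 sig. figs.
REGISTRY: dict[str, Isotope] = {
    "1H": Isotope("1H", 1.000000),
    "13C": Isotope("13C", 0.25145020),
    "31P": Isotope("31P", 0.40480742),
    "77Se": Isotope("77Se", 0.19071513),
    # 15N has negative gamma; included to exercise the sign convention.
    "15N": Isotope("15N", -0.10136767),
}


def get_isotope(name: str | Isotope) -> Isotope:
    """Look up an isotope by name; raises ``KeyError`` listing the registry."""
    if isinstance(name, Isotope):
        return name
    try:
        return REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown isotope {name!r}; registered: {sorted(REGISTRY)}"
        ) from None
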