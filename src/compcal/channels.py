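"""Mass-channel labels.

ICP-MS survey scans index intensities by mass channel, written here as a
mass-number prefix followed by the IUPAC element symbol (``"27Al"``,
``"66Zn"``).  Labels are validated against the NIST isotope table shipped
with :mod:`pyteomics`, so ``"28Al"`` (no such aluminium isotope) is rejected
while radiogenic channels such as ``"99Tc"`` are accepted.
"""

from __future__ import annotations

import re

from pyteomics.mass import nist_mass

from .exceptions import FormatError

_CHANNEL_RE = re.compile(r"^(\d{1,3})([A-Z][a-z]?)$")


def parse_channel(label: str) -> tuple[int, str]:
    """Split a mass-channel label into ``(mass_number, element_symbol)``.

    Raises :class:`FormatError` if the label does not follow the
    ``<mass><Symbol>`` grammar, the symbol is not a known element, or the
    mass number is not a known isotope of that element.
    """
    m = _CHANNEL_RE.match(label.strip())
    if m is None:
        raise FormatError(f"mass-channel label {label!r} is not of the form '<mass><Symbol>'")
    mass, symbol = int(m.group(1)), m.group(2)
    isotopes = nist_mass.get(symbol)
    if isotopes is None:
        raise FormatError(f"unknown element symbol {symbol!r} in channel {label!r}")
    if mass not in isotopes or mass == 0:
        raise FormatError(f"{mass} is not a known isotope mass number of {symbol} (channel {label!r})")
    return mass, symbol


def channel_element(label: str) -> str:
    """Element symbol of a mass-channel label."""
    return parse_channel(label)[1]


def most_abundant_isotope(element: str) -> int:
    """Mass number of the most naturally abundant isotope of ``element``.

    Elements with no stable isotope (abundances all zero) fall back to the
    lightest listed isotope.
    """
    isotopes = nist_mass.get(element)
    if not isotopes:
        raise FormatError(f"unknown element symbol {element!r}")
    candidates = {k: v for k, v in isotopes.items() if k != 0}
    best = max(candidates, key=lambda k: (candidates[k][1], -k))
    return best


def default_channel(element: str) -> str:
    """Canonical channel label for an element: its most abundant isotope."""
    return f"{most_abundant_isotope(element)}{element}"
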