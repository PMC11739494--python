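"""Elemental composition arithmetic for CHNOS molecular formulas.

Monoisotopic atomic masses follow CODATA/AME values at sub-ppb precision;
double-bond equivalents (DBE) use the standard valence formula for neutral
CHNOS molecules, DBE = C - H/2 + N/2 + 1.  Integer DBE encodes the nitrogen
rule (H + N must be even for a neutral CHNOS composition).
"""
from __future__ import annotations

import re
from dataclasses import dataclass

# Monoisotopic masses of the light isotopes, in Da.
MASS_C = 12.0
MASS_H = 1.00782503207
MASS_N = 14.0030740048
MASS_O = 15.9949146196
MASS_S = 31.97207100

#: Mass of a proton corrected for the electron, Da.  Neutral mass of a singly
#: deprotonated [M-H]- ion equals m/z + this constant.
PROTON_MASS = 1.007276466

# CH2 Kendrick scaling constant: nominal/exact mass of the CH2 repeat unit.
KENDRICK_CH2 = 14.0 / 14.01565006414

_FORMULA_RE = re.compile(r"([CHNOS])(\d*)")


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """Neutral CHNOS composition.

    Immutable and hashable so compositions can be used as dictionary keys in
    pathway indices and deduplicated by identity.
    """

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0

    @property
    def neutral_mass(self) -> float:
        """Monoisotopic neutral mass in Da, recomputed from element counts."""
        return (
            self.c * MASS_C
            + self.h * MASS_H
            + self.n * MASS_N
            + self.o * MASS_O
            + self.s * MASS_S
        )

    @property
    def dbe(self) -> float:
        """Double-bond equivalents, C - H/2 + N/2 + 1."""
        return self.c - self.h / 2.0 + self.n / 2.0 + 1.0

    @property
    def hc(self) -> float:
        return self.h / self.c if self.c else float("inf")

    @property
    def oc(self) -> float:
        return self.o / self.c if self.c else float("inf")

    def mz_deprotonated(self) -> float:
        """m/z of the singly deprotonated [M-H]- ion."""
        return self.neutral_mass - PROTON_MASS

    def __str__(self) -> str:
        parts = []
        for sym, count in (("C", self.c), ("H", self.h), ("N", self.n),
                           ("O", self.o), ("S", self.s)):
            if count == 1:
                parts.append(sym)
            elif count > 1:
                parts.append(f"{sym}{count}")
        return "".join(parts)

    @classmethod
    def from_string(cls, text: str) -> "MolecularFormula":
        """Parse a Hill-ish formula string such as ``"C12H14O6"``.

        Only C, H, N, O, S are accepted; anything else is a parse error.
        """
        from .errors import ParseError

        counts = {"C": 0, "H": 0, "N": 0, "O": 0, "S": 0}
        pos = 0
        for m in _FORMULA_RE.finditer(text):
            if m.start() != pos:
                raise ParseError(f"unparseable formula {text!r} at position {pos}")
            counts[m.group(1)] += int(m.group(2) or 1)
            pos = m.end()
        if pos != len(text) or pos == 0:
            raise ParseError(f"unparseable formula {text!r}")
        return cls(c=counts["C"], h=counts["H"], n=counts["N"],
                   o=counts["O"], s=counts["S"])


def kendrick_mass_defect(mz):
    """CH2-based Kendrick mass defect, ceil(KM) - KM in [0, 1).

    Members of a CH2-homologous series share the same value.  Chemically
    plausible CHNOS compositions avoid part of the defect scale, leaving a
    void window (used by noise estimation: peaks there are electronic
    noise, not chemistry)."""
    import numpy as np

    km = np.asarray(mz, dtype=float) * KENDRICK_CH2
    return np.ceil(km) - km


def passes_dom_filters(
    f: MolecularFormula,
    dbe_max: float = 25.0,
    hc_range: tuple[float, float] = (0.3, 2.5),
    oc_max: float = 1.2,
) -> bool:
    """Community-standard plausibility filters for DOM formulas.

    Requires an integer, non-negative DBE (the nitrogen rule), H/C within
    ``hc_range``, O/C at most ``oc_max`` and DBE at most ``dbe_max``.
    """
    dbe = f.dbe
    if dbe < 0 or dbe > dbe_max or dbe != int(dbe):
        return False
    if f.c <= 0 or f.h <= 0:
        return False
    if not (hc_range[0] <= f.hc <= hc_range[1]):
        return False
    if f.oc > oc_max:
        return False
    return True
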