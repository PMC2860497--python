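"""Enrichment-pattern taxonomy for bivariate gene-set fits.

Each fitted module is summarised by the *effective signs* of its three
coefficients: a coefficient counts as +, - only when its (adjusted) p-value
falls strictly below the significance threshold, otherwise it is 0.  The
sign triple (alpha, beta, gamma) then maps onto one of 15 labels:

==========  =====================================================
label       meaning
==========  =====================================================
q1i..q4i    module concentrated in one quadrant, interaction
            significant (evidence beyond the additive effects)
b13, b24    bimodal: genes split between quadrants 1&3 (gamma>0)
            or 2&4 (gamma<0), main effects null
q1f..q4f    quadrant pattern, flat surface (no interaction)
xh, xl      enriched only at high / low X
yh, yl      enriched only at high / low Y
NS          nothing significant
==========  =====================================================

When gamma is significant the quadrant is the one opposite the saddle
point (-beta/gamma, -alpha/gamma): its x-direction is sign(beta*gamma) and
its y-direction sign(alpha*gamma), falling back on the main effect's own
sign when the other main effect is null.  This rule covers all 27 triples,
including the four where a significant interaction coexists with
opposite-sign main effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = ["PatternLabel", "PATTERN_LABELS", "effective_signs", "classify"]

PATTERN_LABELS = (
    "q1i", "q2i", "q3i", "q4i",
    "b13", "b24",
    "q1f", "q2f", "q3f", "q4f",
    "xh", "xl", "yh", "yl",
    "NS",
)

_QUADRANT = {(1, 1): 1, (-1, 1): 2, (-1, -1): 3, (1, -1): 4}


@dataclass(frozen=True)
class PatternLabel:
    """A pattern label together with the sign triple that produced it."""

    label: str
    basis: tuple[int, int, int]  # effective signs of (alpha, beta, gamma)

    def __str__(self) -> str:
        return self.label


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def effective_signs(
    estimates, adjusted_p, threshold: float = 0.05
) -> tuple[int, int, int]:
    """Map (estimate, adjusted p) pairs to signs in {-1, 0, +1}.

    A coefficient is 0 unless its adjusted p-value is strictly below the
    threshold (a p-value exactly at the threshold is non-significant).
    Coefficients absent from a univariate fit may be passed as ``None`` and
    come out 0.
    """
    signs = []
    for est, p in zip(estimates, adjusted_p):
        if est is None or p is None:
            signs.append(0)
            continue
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"adjusted p-value {p} outside [0, 1]")
        signs.append(_sign(est) if p < threshold else 0)
    if len(signs) != 3:
        raise ValueError("expected three (estimate, p) pairs")
    return tuple(signs)


def classify(signs: tuple[int, int, int], fit: Optional[object] = None) -> PatternLabel:
    """Assign the pattern label for an effective sign triple.

    ``fit`` is accepted for interface symmetry but unused: the triple alone
    determines the label (the saddle-opposite quadrant reduces to a sign
    computation).
    """
    a, b, g = signs
    if not all(s in (-1, 0, 1) for s in (a, b, g)):
        raise ValueError(f"signs must be in {{-1, 0, 1}}, got {signs}")
    if g == 0:
        if a and b:
            label = f"q{_QUADRANT[(a, b)]}f"
        elif a:
            label = "xh" if a > 0 else "xl"
        elif b:
            label = "yh" if b > 0 else "yl"
        else:
            label = "NS"
    elif a == 0 and b == 0:
        label = "b13" if g > 0 else "b24"
    else:
        # quadrant opposite the saddle point (-beta/gamma, -alpha/gamma)
        xs = b * g if b != 0 else a
        ys = a * g if a != 0 else b
        label = f"q{_QUADRANT[(xs, ys)]}i"
    return PatternLabel(label=label, basis=(a, b, g))
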