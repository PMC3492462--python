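"""Study design constants for the four-group whole-blood exposure model.

The experimental design crosses an ex vivo 2 Gy X-ray exposure with an LPS
(lipopolysaccharide) inflammation challenge in cultured whole blood, giving
four treatment groups:

* ``N``  — untreated (sham) control
* ``R``  — 2 Gy radiation only
* ``L``  — LPS only (inflammation confounder)
* ``RL`` — 2 Gy radiation plus LPS

The fixed ordering N < R < L < RL is used everywhere a class order is needed
(confusion matrices, tie-breaks, pair enumeration).
"""

from __future__ import annotations

from itertools import combinations

CLASS_ORDER: tuple[str, ...] = ("N", "R", "L", "RL")

#: index of each class in the canonical order, for deterministic tie-breaks
CLASS_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASS_ORDER)}

#: the eight transcripts whose sham and 2 Gy relative-expression ranges are
#: disjoint 24 h after exposure (the "non-overlap" panel)
PANEL_8: tuple[str, ...] = (
    "BBC3", "FDXR", "CDKN1A", "GADD45a", "PCNA", "XPC", "DDB2", "POLH",
)

#: the twelve radiation-responsive transcripts (>2-fold, significant)
PANEL_12: tuple[str, ...] = PANEL_8 + ("BAX", "CCNG1", "LIG1", "RAD51")

#: all assayed target transcripts, including the radiation-unresponsive CHK2
ASSAYED_GENES: tuple[str, ...] = PANEL_12 + ("CHK2",)

#: candidate endogenous-control (reference) genes
REFERENCE_GENES: tuple[str, ...] = ("ACTB", "GAPDH")

#: the phosphoprotein marker measured by ELISA without a standard curve
PROTEIN_MARKER: str = "pCHK2"

#: marker set used for 4-class screening: 8 transcripts + 1 protein
MARKERS_9: tuple[str, ...] = PANEL_8 + (PROTEIN_MARKER,)

#: class pairs in the order the marker filter visits them: pairs involving
#: the untreated class first, then the remaining pairs, lexicographic over
#: the canonical class listing
DEFAULT_PAIR_ORDER: tuple[tuple[str, str], ...] = tuple(
    combinations(CLASS_ORDER, 2)
)


def class_pairs(classes: tuple[str, ...] = CLASS_ORDER) -> tuple[tuple[str, str], ...]:
    """All unordered class pairs, K(K-1)/2 of them, in canonical order."""
    return tuple(combinations(classes, 2))
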