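"""The 14-way EMS structure decision tree.

Coherence is the gatekeeper: nonsignificant coherence means no detectable
structure, significant *negative* coherence (more embedded absences than
chance) means checkerboard mutual exclusivity, and significant *positive*
coherence opens the turnover/boundary-clumping branches.  Significant
negative turnover yields the nested family, significant positive turnover
the gradient family (Clementsian / Gleasonian / evenly spaced by boundary
clumping), and nonsignificant turnover the corresponding "quasi" variants,
with the direction taken from the sign of (observed - simulated mean).
"""

from __future__ import annotations

from dataclasses import dataclass

from .ems import BoundaryClumpResult, MetricResult

__all__ = ["STRUCTURE_LABELS", "StructureLabel", "classify"]

STRUCTURE_LABELS = (
    "checkerboard",
    "no significant structure (random)",
    "nested - clumped species loss",
    "nested - random species loss",
    "nested - hyperdispersed species loss",
    "quasi-nested - clumped species loss",
    "quasi-nested - random species loss",
    "quasi-nested - hyperdispersed species loss",
    "Clementsian",
    "Gleasonian",
    "evenly spaced",
    "quasi-Clementsian",
    "quasi-Gleasonian",
    "quasi-evenly spaced",
)


@dataclass(frozen=True)
class StructureLabel:
    label: str
    rationale: str

    def __post_init__(self) -> None:
        if self.label not in STRUCTURE_LABELS:
            raise ValueError(f"unknown structure label {self.label!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def _clump_variant(prefix_sig: str, prefix_quasi: str | None, clumping, alpha):
    """Pick clumped / random / hyperdispersed wording from the Morisita test."""
    if clumping.p < alpha and clumping.morisita_index > 1:
        return "clumped"
    if clumping.p < alpha and clumping.morisita_index < 1:
        return "hyperdispersed"
    return "random"


def classify(
    coherence: MetricResult,
    turnover: MetricResult | None = None,
    clumping: BoundaryClumpResult | None = None,
    alpha: float = 0.05,
) -> StructureLabel:
    """Map the three metric outcomes onto one of the 14 idealised structures.

    ``turnover`` and ``clumping`` may be omitted only when coherence is
    nonsignificant or negative (the tree short-circuits there).
    """
    if not coherence.significant_at(alpha):
        return StructureLabel(
            "no significant structure (random)",
            f"coherence p={coherence.p:.3g} >= alpha={alpha}",
        )
    if coherence.observed > coherence.sim_mean:
        return StructureLabel(
            "checkerboard",
            f"significant negative coherence (z={coherence.z:.2f}): "
            "more embedded absences than chance",
        )
    if turnover is None or clumping is None:
        raise ValueError(
            "incomplete metric set: positive coherence requires turnover "
            "and boundary clumping results"
        )

    variant = _clump_variant("", None, clumping, alpha)
    turn_positive = turnover.direction == "positive"
    turn_sig = turnover.significant_at(alpha) and not turnover.degenerate

    why = (
        f"coherence z={coherence.z:.2f} (positive); turnover z={turnover.z:.2f} "
        f"p={turnover.p:.3g} ({turnover.direction}); Morisita I="
        f"{clumping.morisita_index:.3g} p={clumping.p:.3g}"
    )

    if turn_sig and not turn_positive:
        return StructureLabel(f"nested - {variant} species loss", why)
    if turn_sig and turn_positive:
        label = {
            "clumped": "Clementsian",
            "hyperdispersed": "evenly spaced",
            "random": "Gleasonian",
        }[variant]
        return StructureLabel(label, why)
    # nonsignificant turnover: quasi family by direction sign
    if not turn_positive:
        return StructureLabel(f"quasi-nested - {variant} species loss", why)
    label = {
        "clumped": "quasi-Clementsian",
        "hyperdispersed": "quasi-evenly spaced",
        "random": "quasi-Gleasonian",
    }[variant]
    return StructureLabel(label, why)


#: Coarse family of each label, used when scoring structure recovery.
LABEL_FAMILY = {
    "checkerboard": "checkerboard",
    "no significant structure (random)": "random",
    "nested - clumped species loss": "nested",
    "nested - random species loss": "nested",
    "nested - hyperdispersed species loss": "nested",
    "quasi-nested - clumped species loss": "nested",
    "quasi-nested - random species loss": "nested",
    "quasi-nested - hyperdispersed species loss": "nested",
    "Clementsian": "clementsian",
    "quasi-Clementsian": "clementsian",
    "Gleasonian": "gleasonian",
    "quasi-Gleasonian": "gleasonian",
    "evenly spaced": "evenly_spaced",
    "quasi-evenly spaced": "evenly_spaced",
}
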