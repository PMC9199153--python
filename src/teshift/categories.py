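"""The seven-way translational-regulation taxonomy.

Between two conditions a background gene falls in exactly one class:

* ``up_te_constant`` / ``down_te_constant`` — mRNA and footprints move
  together, translation efficiency (TE) unchanged ("TE constant" classes).
* ``translationally_induced`` / ``translationally_repressed`` — TE changes
  significantly and footprints change significantly in the same direction.
* ``rna_up_te_down`` / ``rna_down_te_up`` — TE changes significantly while
  footprints do not: mRNA abundance moved and translation buffered it
  ("translational buffering").
* ``unregulated`` — everything else.
"""

from __future__ import annotations

from enum import Enum


class RegulationCategory(str, Enum):
    UP_TE_CONSTANT = "up_te_constant"
    DOWN_TE_CONSTANT = "down_te_constant"
    TRANSLATIONALLY_INDUCED = "translationally_induced"
    TRANSLATIONALLY_REPRESSED = "translationally_repressed"
    RNA_UP_TE_DOWN = "rna_up_te_down"
    RNA_DOWN_TE_UP = "rna_down_te_up"
    UNREGULATED = "unregulated"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: canonical ordering used in summary tables
CATEGORY_ORDER: tuple[RegulationCategory, ...] = tuple(RegulationCategory)

#: the four classes with a significant TE shift
TE_SHIFT_CATEGORIES = (
    RegulationCategory.TRANSLATIONALLY_INDUCED,
    RegulationCategory.TRANSLATIONALLY_REPRESSED,
    RegulationCategory.RNA_UP_TE_DOWN,
    RegulationCategory.RNA_DOWN_TE_UP,
)

#: translational buffering: TE moved because mRNA moved while footprints held
BUFFERING_CATEGORIES = (
    RegulationCategory.RNA_UP_TE_DOWN,
    RegulationCategory.RNA_DOWN_TE_UP,
)

#: TE moved because translation itself moved
TRANSLATION_DRIVEN_CATEGORIES = (
    RegulationCategory.TRANSLATIONALLY_INDUCED,
    RegulationCategory.TRANSLATIONALLY_REPRESSED,
)
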