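"""Shared vocabularies and table schema for cohort landmark data.

The cohort table is long-format: one row per analyzed transverse section
(optionally repeated for replicate landmark placements), keyed by animal,
section, age group, sex, genotype and spinal region, followed by the 14
landmark lengths in micrometres.
"""

from __future__ import annotations

#: The 14 landmark lengths measured per section (all in μm):
#: AP/T — cord anteroposterior/transverse diameters; VWC — ventral white
#: commissure; DMS — dorsal median sulcus; LWM/MWM — lateral/medial white
#: matter; AW/PW — anterior/posterior gray-matter widths; VGC/DGC —
#: ventral/dorsal gray commissures; LVH/RVH/LDH/RDH — left/right
#: ventral/dorsal horn lengths.
LANDMARKS: tuple[str, ...] = (
    "AP", "T", "VWC", "DMS", "LWM", "MWM", "AW",
    "PW", "VGC", "DGC", "LVH", "RVH", "LDH", "RDH",
)

AGE_GROUPS: tuple[str, ...] = ("3wo", "8wo")
SEXES: tuple[str, ...] = ("F", "M")
GENOTYPES: tuple[str, ...] = ("WT", "Pkd2l1-Cre::tdTomato")
REGIONS: tuple[str, ...] = ("cervical", "high_thoracic", "low_thoracic", "lumbar")

META_COLUMNS: tuple[str, ...] = (
    "animal_id", "section_id", "replicate", "age_group", "sex", "genotype", "region",
)

#: Canonical column order of the cohort CSV.
COHORT_COLUMNS: tuple[str, ...] = META_COLUMNS + LANDMARKS

#: Upper sanity bound on any landmark length (μm); transverse mouse cord
#: sections never approach 3 mm.
MAX_LENGTH_UM: float = 3000.0
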