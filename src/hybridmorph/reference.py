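"""Published reference statistics for the admixed rhesus macaque colony.

These constants describe the Chinese x Indian *Macaca mulatta* colony this
package models: the sample composition by pedigree ancestry bin, the group
mean sizes, and the small-sample-corrected coefficients of variation (V*)
per group.  They serve two roles:

1. calibration defaults for :mod:`hybridmorph.synthetic_colony`, so that
   simulated colonies match the real colony's composition, lineage mean
   differences, and dispersion; and
2. reference fixtures for desk checks of the deterministic summary
   machinery (composite derivation, group summaries).

Weight is in kilograms; all lengths are in millimetres.  V* values are
percentages.  Ancestry bins are the fraction of Chinese ancestry recorded
in colony pedigrees, in eighths from 0 (full-bred Indian) to 1 (full-bred
Chinese).
"""

from __future__ import annotations

# (n_female, n_male) per Chinese-ancestry bin; 134 animals total,
# 92 female / 42 male, 19 full-bred Indian, 13 full-bred Chinese,
# 102 hybrids.
COLONY_BIN_COUNTS: dict[float, tuple[int, int]] = {
    0.0: (11, 8),
    0.125: (29, 15),
    0.25: (15, 8),
    0.375: (12, 3),
    0.5: (5, 2),
    0.625: (3, 2),
    0.75: (7, 0),
    0.875: (1, 0),
    1.0: (9, 4),
}

# Group means per measurement: {measurement: (indian, chinese, hybrid)}.
# Composites (forelimb = humerus + radius, hindlimb = femur + tibia) are the
# published per-individual composite means; for hybrids they differ slightly
# from the sums of the component means because per-measurement availability
# differed between individuals.
GROUP_MEANS: dict[str, tuple[float, float, float]] = {
    "weight": (16.02, 12.78, 13.08),
    "crown_rump": (583.00, 575.13, 552.19),
    "humerus": (165.91, 180.61, 164.55),
    "femur": (196.14, 209.96, 193.61),
    "radius": (160.65, 176.49, 158.89),
    "tibia": (177.17, 192.09, 175.75),
    "forelimb": (326.56, 357.10, 321.89),
    "hindlimb": (373.30, 402.05, 367.64),
}

# Corrected coefficients of variation V* (percent) per group:
# {measurement: (indian, chinese, hybrid)}.
GROUP_VSTAR: dict[str, tuple[float, float, float]] = {
    "weight": (21.27, 16.02, 19.34),
    "crown_rump": (4.07, 2.64, 4.05),
    "humerus": (4.79, 3.93, 3.59),
    "femur": (3.97, 4.76, 3.79),
    "radius": (4.76, 5.24, 4.25),
    "tibia": (4.81, 5.42, 4.06),
}


def parental_means(measurement: str) -> tuple[float, float]:
    """(Indian mean, Chinese mean) for one measurement."""
    mi, mc, _ = GROUP_MEANS[measurement]
    return mi, mc
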