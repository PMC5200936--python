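"""Published lineage-level reference statistics of the eukaryotic digital
proteome (RefSeq release 70 survey; 492 species, 14 phylogenetic groups).

These printed summary values serve as inputs for desk-scale consistency
checks — evaluating the published hyperplane, refitting it on the 14 group
rows, the percentage contrasts between lineages, and the per-species
protein-count arithmetic — and as the group profiles the synthetic-data
generator emulates.
"""

from __future__ import annotations

import pandas as pd

#: Phylogenetic coverage: species count, total proteins, and total exons per
#: group.  "avg_proteins" is the printed per-species average for the group.
GROUP_CENSUS = pd.DataFrame(
    [
        # group, n_species, total_proteins, avg_proteins, total_exons
        ("Alveolata", 24, 166_806, 6_950, 596_916),
        ("Amoebozoa", 7, 70_337, 10_048, 218_096),
        ("Chlorophyta", 9, 78_172, 8_686, 424_697),
        ("Choanoflagellida", 2, 19_817, 9_909, 164_858),
        ("Cryptophyta", 4, 22_383, 5_596, 146_349),
        ("Excavata", 12, 160_927, 13_411, 171_251),
        ("Fungi", 143, 1_303_212, 9_113, 4_285_632),
        ("Haptophyta", 1, 31_735, 31_735, 118_186),
        ("Ichthyosporea", 1, 8_510, 8_510, 40_799),
        ("Metazoa", 228, 5_743_160, 25_189, 58_003_499),
        ("Nucleariida", 1, 6_115, 6_115, 29_416),
        ("Rhodophyta", 3, 21_255, 7_085, 39_453),
        ("Stramenopila", 11, 175_058, 15_914, 614_663),
        ("Streptophyta", 46, 1_692_582, 36_795, 9_571_726),
    ],
    columns=["group", "n_species", "total_proteins", "avg_proteins", "total_exons"],
)

#: Group-level protein length (aa), exon number, and exon length (nt):
#: means and medians for the 14 groups.
GROUP_ARCHITECTURE = pd.DataFrame(
    [
        # group, mean_pl, median_pl, mean_en, median_en, mean_el, median_el
        ("Alveolata", 535, 364, 3.6, 2, 449, 161),
        ("Amoebozoa", 463, 351, 3.1, 2, 448, 192),
        ("Chlorophyta", 490, 369, 5.4, 3, 270, 139),
        ("Choanoflagellida", 648, 459, 8.2, 6, 237, 113),
        ("Cryptophyta", 435, 316, 6.5, 5, 199, 82),
        ("Excavata", 471, 334, 1.1, 1, 1330, 935),
        ("Fungi", 462, 381, 3.3, 2, 421, 195),
        ("Haptophyta", 367, 294, 3.7, 3, 295, 164),
        ("Ichthyosporea", 637, 494, 4.8, 4, 398, 152),
        ("Metazoa", 595, 439, 10.1, 7, 176, 126),
        ("Nucleariida", 690, 499, 4.8, 4, 429, 216),
        ("Rhodophyta", 411, 334, 1.9, 1, 665, 330),
        ("Stramenopila", 467, 356, 3.5, 2, 399, 196),
        ("Streptophyta", 436, 363, 5.7, 4, 230, 128),
    ],
    columns=["group", "mean_pl", "median_pl", "mean_en", "median_en", "mean_el", "median_el"],
)

#: Overall census totals as printed (species, proteins, per-species average).
TOTAL_SPECIES = 492
TOTAL_PROTEINS = 9_522_269
TOTAL_EXONS = 74_425_541
PRINTED_AVG_PROTEINS_PER_SPECIES = 19_354

#: Endosymbiotic dilution scenario: migrant cyanobacterial proteins blended
#: into a hypothetical ancestral eukaryotic proteome.
DILUTION_N_MIGRANT = 3_500
DILUTION_MEAN_MIGRANT_AA = 319.0
DILUTION_N_HOST = 22_900
DILUTION_MEAN_HOST_AA = 472.0

#: Plant-nucleus vs cyanobacterial ortholog comparison (1339 pairs):
#: endosymbiotic plant proteins average 473 aa vs 314 aa for orthologs.
ORTHOLOG_N_PAIRS = 1_339
ORTHOLOG_MEAN_PLANT_AA = 473.0
ORTHOLOG_MEAN_CYANO_AA = 314.0
ORTHOLOG_MEAN_SHIFT_AA = 159.0


def architecture_rows() -> pd.DataFrame:
    """The 14 group rows keyed as a length-model design table."""
    return GROUP_ARCHITECTURE.rename(columns={})[
        ["group", "mean_pl", "mean_en", "mean_el"]
    ].copy()
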