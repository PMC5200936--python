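"""Synthetic GenBank proteomes and related fixtures.

The generator emulates the statistical structure of an annotated eukaryotic
proteome so every pipeline stage can be exercised without downloading real
genomes.  Per species it draws:

* protein length L (aa) from a lognormal whose mu/sigma are tied to a target
  (mean, median) pair — sigma = sqrt(2 ln(mean/median)), mu = ln(median) —
  so a group profile taken from the published lineage tables reproduces both
  statistics in expectation;
* exon count per gene as 1 + Poisson(mean_en - 1), which matches the target
  mean with modest dispersion and guarantees at least one exon;
* an exon partition of the coding length 3(L+1) nt (stop codon included)
  into the drawn number of positive parts, uniformly at random;
* genomic coordinates with intron gaps uniform in [50, 500] nt (cosmetic:
  only exon arithmetic is consumed downstream) and a random strand.

Each species becomes one GenBank record whose CDS features carry
``join(...)`` locations and consistent ``/translation`` qualifiers, together
with a truth table of everything drawn.  All randomness flows from explicit
seeds; no global random state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

import math
import io
import logging
import zlib

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupProfile:
    """Target architecture of one lineage's synthetic proteomes."""

    group: str
    mean_pl: float  # aa
    median_pl: float  # aa
    mean_en: float  # exons per gene, >= 1
    n_species: int = 5
    genes_per_species: int = 2000
    intron_min: int = 50
    intron_max: int = 500

    def __post_init__(self) -> None:
        if not self.mean_pl >= self.median_pl > 0:
            raise ValueError("right-skew requires mean_pl >= median_pl > 0")
        if self.mean_en < 1:
            raise ValueError("mean exon number must be >= 1")

    @property
    def sigma(self) -> float:
        """Lognormal sigma implied by the mean/median ratio."""
        return math.sqrt(2.0 * math.log(self.mean_pl / self.median_pl))

    @property
    def mu(self) -> float:
        return math.log(self.median_pl)


#: Profiles mirroring the two headline lineages of the published survey:
#: animals (many short exons) vs land plants (fewer, larger exons).
METAZOA_LIKE = GroupProfile("Metazoa", mean_pl=595, median_pl=439, mean_en=10.1)
STREPTOPHYTA_LIKE = GroupProfile("Streptophyta", mean_pl=436, median_pl=363, mean_en=5.7)


def _partition(total: int, parts: int, rng: np.random.Generator) -> np.ndarray:
    """Split ``total`` into ``parts`` positive integers uniformly at random."""
    if parts == 1:
        return np.array([total])
    cuts = np.sort(rng.choice(total - 1, size=parts - 1, replace=False) + 1)
    return np.diff(np.concatenate(([0], cuts, [total])))


def simulate_species_genbank(
    profile: GroupProfile,
    species: str,
    seed: int,
    n_genes: int | None = None,
) -> tuple[str, pd.DataFrame]:
    """One species' GenBank record text plus the truth table of drawn values.

    Deterministic for a given (profile, species, seed); genes whose drawn
    exon count exceeds the available coding nucleotides are re-drawn (and
    logged), which can only matter for extremely short proteins.
    """
    rng = np.random.default_rng(seed)
    n = n_genes if n_genes is not None else profile.genes_per_species
    # short, stable, unique-per-species accession that fits the LOCUS field
    accession = f"SYN{zlib.crc32(species.encode()) & 0xFFFFFFFF:08X}"

    features = []
    truth_rows = []
    cursor = int(rng.integers(200, 2000))
    for i in range(n):
        L = max(1, int(round(rng.lognormal(profile.mu, profile.sigma))))
        nt = 3 * (L + 1)
        for _ in range(100):
            k = 1 + rng.poisson(profile.mean_en - 1.0)
            if k <= nt:
                break
            logger.debug("resampled exon count for %s gene %d", species, i)
        exon_lengths = _partition(nt, k, rng)
        strand = 1 if rng.random() < 0.5 else -1

        starts = []
        pos = int(cursor)
        for el in exon_lengths:
            starts.append(int(pos))
            pos += int(el) + int(rng.integers(profile.intron_min, profile.intron_max + 1))
        gene_end = starts[-1] + int(exon_lengths[-1])
        cursor = gene_end + int(rng.integers(200, 2000))

        parts = [
            SimpleLocation(s - 1, s - 1 + int(el), strand)
            for s, el in zip(starts, exon_lengths)
        ]
        if strand == -1:
            parts = parts[::-1]  # store in translation order
        loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        protein_id = f"{accession}_P{i + 1:05d}"
        translation = "M" + "A" * (L - 1)
        features.append(
            SeqFeature(
                loc,
                type="CDS",
                qualifiers={
                    "protein_id": [protein_id],
                    "translation": [translation],
                    "codon_start": ["1"],
                },
            )
        )
        tl_order = exon_lengths[::-1] if strand == -1 else exon_lengths
        truth_rows.append(
            {
                "species": species,
                "group": profile.group,
                "protein_id": protein_id,
                "protein_aa": L,
                "cds_nt": nt,
                "n_exons": int(k),
                "exon_lengths": ",".join(str(int(x)) for x in tl_order),
                "strand": "reverse" if strand == -1 else "forward",
            }
        )

    record = SeqRecord(Seq(None, length=int(cursor + 100)), id=accession, name=accession)
    record.description = f"{species} synthetic digital proteome"
    record.annotations["molecule_type"] = "DNA"
    record.annotations["organism"] = species
    record.annotations["source"] = species
    record.features = [
        SeqFeature(SimpleLocation(0, int(cursor + 100), 1), type="source",
                   qualifiers={"organism": [species]})
    ] + features
    handle = io.StringIO()
    SeqIO.write(record, handle, "genbank")
    return handle.getvalue(), pd.DataFrame(truth_rows)


def simulate_dataset(
    profiles: list[GroupProfile],
    out_dir: str | Path,
    seed: int,
) -> dict:
    """Write a multi-group synthetic dataset to ``out_dir``.

    Produces one GenBank file per species, a ``groups.tsv`` species-to-group
    map, a combined ``truth.tsv``, and a ``manifest.json`` recording the
    seed and per-species counts.  Returns the manifest dict.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_rng = np.random.default_rng(seed)
    species_seen: set[str] = set()
    group_rows = []
    truths = []
    manifest: dict = {"seed": int(seed), "species": []}
    for profile in profiles:
        for j in range(profile.n_species):
            species = f"{profile.group} synthspecies{j + 1}"
            if species in species_seen:
                raise ValueError(f"duplicate species name {species!r}")
            species_seen.add(species)
            sp_seed = int(root_rng.integers(0, 2**31 - 1))
            text, truth = simulate_species_genbank(profile, species, sp_seed)
            fname = species.replace(" ", "_") + ".gbk"
            (out / fname).write_text(text)
            truths.append(truth)
            group_rows.append({"species": species, "group": profile.group})
            manifest["species"].append(
                {
                    "species": species,
                    "group": profile.group,
                    "file": fname,
                    "n_genes": int(len(truth)),
                    "seed": sp_seed,
                }
            )
    pd.DataFrame(group_rows).to_csv(out / "groups.tsv", sep="\t", index=False)
    pd.concat(truths, ignore_index=True).to_csv(out / "truth.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def simulate_ortholog_pairs(
    n: int,
    base_mean: float = 314.0,
    shift: float = 159.0,
    sd: float = 50.0,
    seed: int = 0,
    sigma: float = 0.6,
) -> pd.DataFrame:
    """Synthetic plant/cyanobacterium ortholog length pairs.

    Cyanobacterial lengths are lognormal with the requested arithmetic mean
    (mu = ln(base_mean) - sigma^2/2); plant lengths add a Normal(shift, sd)
    offset, floored at 1 aa.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cyano = np.maximum(
        1.0, np.round(rng.lognormal(math.log(base_mean) - sigma**2 / 2.0, sigma, n))
    )
    plant = np.maximum(1.0, np.round(cyano + rng.normal(shift, sd, n)))
    return pd.DataFrame({"plant_aa": plant, "cyano_aa": cyano})


def worked_example_fixture() -> str:
    """A minimal GenBank record with the canonical three-exon CDS.

    The single CDS of XP_007325329.1 (*Agaricus bisporus*) joins exons
    18,372..18,786, 18,829..19,191 and 19,447..19,622 — lengths 415, 363 and
    176 nt, i.e. 954 coding nt and a 317-aa translation — and passes QC.
    """
    spans = [(18372, 18786), (18829, 19191), (19447, 19622)]
    parts = [SimpleLocation(s - 1, e, 1) for s, e in spans]
    nt = sum(e - s + 1 for s, e in spans)
    aa = nt // 3 - 1
    record = SeqRecord(Seq(None, length=20000), id="SYN_AGABI01", name="SYN_AGABI01")
    record.description = "Agaricus bisporus worked-example fixture"
    record.annotations["molecule_type"] = "DNA"
    record.annotations["organism"] = "Agaricus bisporus"
    record.annotations["source"] = "Agaricus bisporus"
    record.features = [
        SeqFeature(SimpleLocation(0, 20000, 1), type="source",
                   qualifiers={"organism": ["Agaricus bisporus"]}),
        SeqFeature(
            CompoundLocation(parts),
            type="CDS",
            qualifiers={
                "protein_id": ["XP_007325329.1"],
                "translation": ["M" + "A" * (aa - 1)],
                "codon_start": ["1"],
            },
        ),
    ]
    handle = io.StringIO()
    SeqIO.write(record, handle, "genbank")
    return handle.getvalue()
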