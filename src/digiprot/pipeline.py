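"""End-to-end orchestration: GenBank files in, summary tables and tests out.

``run_pipeline`` chains the stages — ingest + QC, per-species summaries,
per-group summaries, cross-group Kruskal-Wallis with letters, and the
protein-length hyperplane fit — writing each stage's table plus a manifest
that reconciles record counts (ingested = retained + excluded) and records
the seed and configuration.  Re-running with identical inputs and config is
bit-identical: every stage is deterministic.
"""

from __future__ import annotations

import glob as globmod
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import genbank, lengthmodel, stats, summary

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genbank: list[str]  # paths or globs of GenBank flat files
    groups: str | None = None  # species -> group TSV
    out_dir: str = "digiprot_out"
    min_per_species: int = 500
    convention: str = "pooled"  # exon-length averaging convention
    level: str = "both"  # pooled_proteins | species_means | both
    alpha: float = 0.05
    interaction: bool = True
    seed: int = 0

    def resolve_inputs(self) -> list[Path]:
        paths: list[Path] = []
        for pattern in self.genbank:
            hits = sorted(globmod.glob(pattern))
            if hits:
                paths.extend(Path(h) for h in hits)
            elif Path(pattern).exists():
                paths.append(Path(pattern))
            else:
                raise FileNotFoundError(f"no input matches {pattern!r}")
        if not paths:
            raise FileNotFoundError("no GenBank inputs found")
        if self.groups is not None and not Path(self.groups).exists():
            raise FileNotFoundError(self.groups)
        return paths


def _read_group_map(path: str | None) -> dict[str, str] | None:
    if path is None:
        return None
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["species"], df["group"]))


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the output directory."""
    paths = config.resolve_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    group_map = _read_group_map(config.groups)

    # --- ingest + QC
    proteomes = genbank.ingest_genbank(paths, group_map=group_map)
    retained: list[genbank.SpeciesProteome] = []
    qc_entries = []
    for pt in proteomes:
        filtered, report = genbank.qc_filter(pt, config.min_per_species)
        qc_entries.append(
            {
                "species": pt.species,
                "n_input": report.n_input,
                "n_retained": report.n_retained,
                "n_excluded": report.n_excluded,
                "species_dropped": report.species_dropped,
                "flag_counts": report.flag_counts,
            }
        )
        if filtered.retained:
            retained.append(filtered)
    genbank.write_records_tsv(retained, out / "records.tsv")

    # --- per-species summaries
    summaries = [
        summary.species_summary(pt.records, convention=config.convention)
        for pt in retained
    ]
    sp_frame = summary.summaries_frame(summaries)
    sp_frame.to_csv(out / "species_summary.tsv", sep="\t", index=False)

    # --- per-group summaries
    by_group: dict[str, list] = {}
    for s in summaries:
        by_group.setdefault(s.group or "ungrouped", []).append(s)
    levels = (
        ["species_means", "pooled_proteins"]
        if config.level == "both"
        else [config.level]
    )
    all_records = genbank.records_table(retained)
    group_rows = []
    for level in levels:
        for grp, ss in sorted(by_group.items()):
            gs = summary.group_summary(
                ss,
                level=level,  # type: ignore[arg-type]
                records=all_records if level == "pooled_proteins" else None,
            )
            group_rows.append(vars(gs))
    pd.DataFrame(group_rows).to_csv(out / "group_summary.tsv", sep="\t", index=False)

    # --- cross-group protein-length comparison
    letters_payload = {}
    if len(by_group) >= 2:
        samples = {}
        for pt in retained:
            grp = pt.group or "ungrouped"
            vals = [r.protein_length for r in pt.records if r.protein_length]
            samples.setdefault(grp, []).extend(vals)
        kw = stats.kruskal_wallis(*samples.values())
        pw = stats.pairwise_posthoc(samples)
        medians = {g: float(pd.Series(v).median()) for g, v in samples.items()}
        order = sorted(samples, key=lambda g: -medians[g])
        display = stats.compact_letters(pw, alpha=config.alpha, order=order)
        pd.DataFrame(
            [{"H": kw.H, "df": kw.df, "p": kw.p}]
        ).to_csv(out / "kw.tsv", sep="\t", index=False)
        pw.to_csv(out / "pairwise.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"group": g, "letters": display.letters[g], "median_pl": medians[g]}
             for g in order]
        ).to_csv(out / "letters.tsv", sep="\t", index=False)
        letters_payload = display.letters

    # --- hyperplane fit over species means
    model_payload = None
    n_coef = 4 if config.interaction else 3
    if len(sp_frame) >= n_coef:
        model = lengthmodel.fit_length_model(
            sp_frame.rename(columns={"mean_el_pooled": "mean_el"}),
            interaction=config.interaction,
        )
        model_payload = {
            "intercept": model.intercept,
            "beta_el": model.beta_el,
            "beta_en": model.beta_en,
            "beta_interaction": model.beta_interaction,
            "r_squared": model.r_squared,
            "n_obs": model.n_obs,
        }
        (out / "model.json").write_text(json.dumps(model_payload, indent=2))

    manifest = {
        "config": {**vars(config)},
        "inputs": [str(p) for p in paths],
        "seed": config.seed,
        "qc": qc_entries,
        "n_species_ingested": len(proteomes),
        "n_species_retained": len(retained),
        "n_records_retained": int(sum(pt.n_records for pt in retained)),
        "letters": letters_payload,
        "model": model_payload,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info(
        "pipeline done: %d/%d species retained", len(retained), len(proteomes)
    )
    return out
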