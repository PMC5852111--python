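"""End-to-end orchestration and the run report.

``run_pipeline`` executes simulation (or table loading), PSM filtering,
protein inference, quantitation, transmembrane consensus scanning, and
DAMP calling for both genotypes, then assembles a report of every
checkpoint quantity (stage counts, replicate Venn overlaps, regression
slopes, internal-error cutoffs, membrane-protein fractions, DAMP
strata, and the cross-genotype overlap table).  Auxiliary helpers:
7-region Venn accounting and peroxidase activity units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import dampcall, identification, quantify, synthdata, tmconsensus
from .identification import FilterParams
from .quantify import CutoffParams
from .synthdata import GENOTYPES, SimulationConfig
from .tmconsensus import PredictorParams


@dataclass
class PipelineConfig:
    simulate: SimulationConfig | None = None
    psm_path: str | None = None
    fasta_path: str | None = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    predictor_params: PredictorParams = field(default_factory=PredictorParams)
    cutoff: CutoffParams = field(default_factory=CutoffParams)
    use_derived_cutoff: bool = False
    outdir: str | None = None

    def __post_init__(self):
        if self.simulate is None and (self.psm_path is None or self.fasta_path is None):
            raise ValueError(
                "config needs either a simulate block or both psm_path and fasta_path"
            )


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML mapping of the dataclass fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "simulate" in raw and raw["simulate"] is not None:
        kwargs["simulate"] = SimulationConfig(**raw["simulate"])
    for key in ("psm_path", "fasta_path", "outdir", "use_derived_cutoff"):
        if key in raw:
            kwargs[key] = raw[key]
    if "filter_params" in raw:
        kwargs["filter_params"] = FilterParams(**raw["filter_params"])
    if "predictor_params" in raw:
        kwargs["predictor_params"] = PredictorParams(**raw["predictor_params"])
    if "cutoff" in raw:
        kwargs["cutoff"] = CutoffParams(**raw["cutoff"])
    return PipelineConfig(**kwargs)


def venn_counts(id_sets: Sequence[set]) -> tuple[dict[str, int], int]:
    """7-region Venn counts for three sets plus the triple-overlap percent.

    The triple-overlap fraction is |A∩B∩C| / |A∪B∪C| as a nearest
    integer percentage (the union is the denominator).
    """
    if len(id_sets) != 3:
        raise ValueError("venn_counts expects exactly three sets")
    a, b, c = (set(s) for s in id_sets)
    union = a | b | c
    triple = a & b & c
    regions = {
        "only_a": len(a - b - c),
        "only_b": len(b - a - c),
        "only_c": len(c - a - b),
        "ab": len((a & b) - c),
        "ac": len((a & c) - b),
        "bc": len((b & c) - a),
        "abc": len(triple),
    }
    pct = (
        dampcall.round_half_away(100.0 * len(triple) / len(union)) if union else 0
    )
    return regions, pct


def activity_units(delta_a_per_min: float, mg_protein: float) -> float:
    """Peroxidase activity in U per mg protein.

    One activity unit is a 0.01 absorbance increase per minute; negative
    absorbance changes clamp to zero activity with a warning.
    """
    if mg_protein <= 0:
        raise ValueError("mg_protein must be > 0")
    if delta_a_per_min < 0:
        warnings.warn("negative absorbance change; activity clamped to 0", stacklevel=2)
        return 0.0
    return (delta_a_per_min / 0.01) / mg_protein


def _per_set_sets(
    frame: pd.DataFrame, replicate_sets: Sequence[str], key: str = "protein_id"
) -> list[set]:
    return [
        set(frame.loc[frame["replicate_set"] == rep, key]) for rep in replicate_sets
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run report (JSON-serialisable).

    Stage outputs (PSM tables, quant tables, TM scan, DAMP calls,
    overlap table, report) are written under ``config.outdir`` when set.
    """
    if config.simulate is not None:
        proteome, truths, psms = synthdata.generate_study(config.simulate)
    else:
        proteome = synthdata.read_fasta(config.fasta_path)
        psms = synthdata.read_psm_table(config.psm_path)
        truths = None

    scan = tmconsensus.scan_proteome(proteome, config.predictor_params)
    membrane = tmconsensus.membrane_ids(scan)

    report: dict = {"genotypes": {}, "params": {
        "min_score": config.filter_params.min_score,
        "max_fdr": config.filter_params.max_fdr,
        "min_unique_peptides": config.filter_params.min_unique_peptides,
        "fold_cutoff": config.cutoff.fold_cutoff,
        "p_threshold": config.cutoff.p_threshold,
        "use_derived_cutoff": config.use_derived_cutoff,
    }}
    calls_by_genotype: dict[str, pd.DataFrame] = {}
    quants: dict[str, pd.DataFrame] = {}
    rep_labels = sorted(psms["replicate_set"].unique())
    n_sets = len(rep_labels)

    for genotype in sorted(psms["genotype"].unique()):
        gp = psms[psms["genotype"] == genotype]
        filtered, filt_report = identification.filter_psms(
            gp, config.filter_params, return_report=True
        )
        inferred = identification.infer_proteins(
            filtered, config.filter_params.min_unique_peptides
        )
        qpsms = identification.quantifiable_psms(filtered, inferred)
        quant = quantify.add_pvalues(
            quantify.protein_quant_table(qpsms), n_replicate_sets=n_sets
        )
        quants[genotype] = quant

        identified_sets = _per_set_sets(filtered[~filtered["is_decoy"]], rep_labels)
        quantified_sets = _per_set_sets(quant, rep_labels)
        id_regions, id_pct = venn_counts(identified_sets) if n_sets == 3 else ({}, None)
        q_regions, q_pct = venn_counts(quantified_sets) if n_sets == 3 else ({}, None)

        in_all = set.intersection(*quantified_sets) if quantified_sets else set()
        mem_quant = in_all & membrane
        qc = quantify.qc_report(quant, genotype)

        cutoff = config.cutoff
        if config.use_derived_cutoff and qc["d_log2"] is not None:
            cutoff = CutoffParams(d_log2=qc["d_log2"], p_threshold=config.cutoff.p_threshold)
        calls = dampcall.call_damps(quant, membrane, cutoff, n_replicate_sets=n_sets)
        calls_by_genotype[genotype] = calls

        damp_strata = {
            f"{tp}_{d}": int(
                (
                    (calls["timepoint"] == tp) & (calls["direction"] == d)
                ).sum()
            )
            for tp in dampcall.TIMEPOINTS
            for d in dampcall.DIRECTIONS
        }
        n_quant_all = len(in_all)
        n_mem = len(mem_quant)
        report["genotypes"][genotype] = {
            "n_psms_in": int(len(gp)),
            "n_psms_filtered": int(len(filtered)),
            "filter": filt_report.to_dict(orient="records"),
            "n_identified_union": int(
                filtered.loc[~filtered["is_decoy"], "protein_id"].nunique()
            ),
            "identified_venn": id_regions,
            "identified_triple_pct": id_pct,
            "n_quantified_union": int(quant["protein_id"].nunique()),
            "quantified_venn": q_regions,
            "quantified_triple_pct": q_pct,
            "n_quantified_all_sets": n_quant_all,
            "n_membrane_proteins": n_mem,
            "mp_fraction_pct": (
                round(100.0 * n_mem / n_quant_all, 1) if n_quant_all else None
            ),
            "slopes": qc["slopes"],
            "d_log2": qc["d_log2"],
            "derived_fold_cutoff": qc["fold_cutoff"],
            "fold_cutoff_used": cutoff.fold_cutoff,
            "damp_strata": damp_strata,
            "n_damps_distinct": int(
                calls.loc[calls["direction"] != "unchanged", "protein_id"].nunique()
            ),
        }

    gts = sorted(calls_by_genotype)
    if len(gts) == 2:
        overlap = dampcall.overlap_table(
            calls_by_genotype[gts[0]], calls_by_genotype[gts[1]]
        )
        report["overlap"] = overlap.to_dict(orient="records")
        report["damp_summary"] = dampcall.damp_protein_summary(
            calls_by_genotype[gts[0]], calls_by_genotype[gts[1]]
        )
    else:
        overlap = None

    report["n_proteome"] = len(proteome)
    report["n_membrane_predicted"] = int(len(membrane))

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "proteome.fasta").write_text(synthdata.proteome_to_fasta(proteome))
        synthdata.write_psm_table(psms, out / "psms.tsv")
        scan.to_csv(out / "tmscan.tsv", sep="\t", index=False)
        for g, quant in quants.items():
            quant.to_csv(out / f"protein_quant_{g}.tsv", sep="\t", index=False)
            calls_by_genotype[g].to_csv(out / f"damp_calls_{g}.tsv", sep="\t", index=False)
        if overlap is not None:
            overlap.to_csv(out / "overlap_table.tsv", sep="\t", index=False)
        if truths is not None:
            pd.concat(
                [synthdata.truth_table(truths[g]) for g in truths]
            ).to_csv(out / "truth.tsv", sep="\t", index=False)
        (out / "run_report.json").write_text(json.dumps(report, indent=2))

    _check_report_percentages(report)
    return report


def _check_report_percentages(report: dict) -> None:
    """Every reported percentage must recompute from its own counts."""
    for g, rep in report.get("genotypes", {}).items():
        if rep["mp_fraction_pct"] is not None:
            expect = round(
                100.0 * rep["n_membrane_proteins"] / rep["n_quantified_all_sets"], 1
            )
            assert rep["mp_fraction_pct"] == expect, g
        for key in ("identified", "quantified"):
            regions = rep[f"{key}_venn"]
            pct = rep[f"{key}_triple_pct"]
            if regions and pct is not None:
                union = sum(regions.values())
                assert pct == dampcall.round_half_away(
                    100.0 * regions["abc"] / union
                ) if union else pct == 0
    for row in report.get("overlap", []):
        assert row["unique_a"] == row["total_a"] - row["common"]
        assert row["unique_b"] == row["total_b"] - row["common"]
        assert row["common_pct"] == dampcall.union_percentage(
            row["total_a"], row["total_b"], row["common"]
        )
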