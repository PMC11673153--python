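"""End-to-end orchestration of the uniparental-marker analysis.

``run_pipeline`` executes the stages in dependency order — sequence
haplotyping, contingency building, family assignment, retention,
pedigree statistics, MSY typing — writes every stage's table to the
output directory, and collates a machine-readable ``summary.json``
with SHA-256 checksums of all outputs.  Stage outputs are pure
functions of the configuration, the inputs and the seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from studlines import io
from studlines.families import (
    NoDataError,
    assign_families,
    build_contingency,
    haplotype_frequencies,
    matching_oracle,
    retention,
)
from studlines.fixtures import ascal_stallions, build_motif_catalogue, table1_records
from studlines.mito import HaplotypeCatalogue, anchor_align, call_haplotype
from studlines.msy import MsyGenotype, call_msy, msy_frequencies
from studlines.pedigree import gene_origin_summary
from studlines.reference import ReferenceMap, synthetic_dloop_reference
from studlines.simulate import StudScenario, emit_msy, emit_sequences, simulate_stud

logger = logging.getLogger("studlines")

__all__ = ["run_pipeline", "haplotype_sequences", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


def haplotype_sequences(
    samples: list[tuple[str, str]],
    ref: ReferenceMap,
    catalogue: HaplotypeCatalogue,
    *,
    max_distance_fraction: float = 0.25,
    min_overlap: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align and haplotype-call (sample_id, sequence) pairs.

    Returns a call table (sample_id, haplotype, matches, minted) and a
    variant table (sample_id, position, ref, alt, kind).
    """
    calls, var_rows = [], []
    for sample_id, seq in samples:
        res, variants = anchor_align(
            seq, ref, max_distance_fraction=max_distance_fraction, min_overlap=min_overlap
        )
        call = call_haplotype(variants, res.coverage, catalogue)
        calls.append(
            {
                "sample_id": sample_id,
                "haplotype": call.name,
                "matches": ";".join(call.matches),
                "minted": call.minted,
                "n_variants": len(variants),
            }
        )
        for v in variants:
            var_rows.append(
                {
                    "sample_id": sample_id,
                    "position": v.position,
                    "ref": v.ref_allele,
                    "alt": v.alt_allele,
                    "kind": v.kind,
                }
            )
    call_df = pd.DataFrame(calls, columns=["sample_id", "haplotype", "matches", "minted", "n_variants"])
    var_df = pd.DataFrame(var_rows, columns=["sample_id", "position", "ref", "alt", "kind"])
    return call_df, var_df


def _write(df: pd.DataFrame, path: Path, outputs: dict) -> None:
    df.to_csv(path, index=False)
    outputs[path.name] = io.sha256_of(path)


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the configured analysis; returns the summary dictionary.

    Configuration keys: ``seed`` (required), ``input`` (one of
    ``{"mode": "table1"}``, ``{"mode": "simulate", "scenario": {...}}``
    or ``{"mode": "mares_csv", "path": ...}``), optional ``haplotyping``
    parameters, ``assignment: {oracle: bool}``, ``pedstats:
    {replicates: int}`` and ``msy: {genotypes: path}``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if "seed" not in config:
        raise ValueError("config requires an explicit seed")
    seed = int(config["seed"])
    mode = config.get("input", {}).get("mode", "table1")
    hap_cfg = config.get("haplotyping", {})
    outputs: dict[str, str] = {}
    summary: dict = {"mode": mode, "seed": seed}
    ref = synthetic_dloop_reference()
    catalogue = build_motif_catalogue(ref)

    # ---- stage: inputs -> mare table (sample_id, family, haplotype) -----
    stage = "inputs"
    try:
        sim = None
        if mode == "table1":
            fixture = table1_records()
            seqs = emit_sequences([(s, h) for s, _, h in fixture], catalogue, ref)
            call_df, var_df = haplotype_sequences(
                [(r.id, str(r.seq)) for r in seqs], ref, catalogue, **hap_cfg
            )
            fam = {s: f for s, f, _ in fixture}
            mares = call_df[["sample_id", "haplotype"]].copy()
            mares["family"] = mares["sample_id"].map(fam)
        elif mode == "simulate":
            scen_cfg = dict(config["input"].get("scenario", {}))
            scen_cfg.setdefault("seed", seed)
            scenario = StudScenario(**scen_cfg)
            sim = simulate_stud(scenario)
            seqs = emit_sequences(
                [(i, sim.haplotype[i]) for i in sim.mares], catalogue, ref
            )
            call_df, var_df = haplotype_sequences(
                [(r.id, str(r.seq)) for r in seqs], ref, catalogue, **hap_cfg
            )
            mares = call_df[["sample_id", "haplotype"]].copy()
            mares["family"] = mares["sample_id"].map(sim.recorded_family)
        elif mode == "mares_csv":
            df = io.read_mares_csv(config["input"]["path"])
            if "haplotype" not in df.columns:
                raise ValueError("mares_csv mode expects a haplotype column")
            mares = df[["sample_id", "family", "haplotype"]]
            call_df = var_df = None
        else:
            raise ValueError(f"unknown input mode {mode!r}")
        mares = mares[["sample_id", "family", "haplotype"]]
        if call_df is not None:
            _write(call_df, out_dir / "haplotype_calls.csv", outputs)
            _write(var_df, out_dir / "variants.csv", outputs)
        _write(mares, out_dir / "mares.csv", outputs)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, exc) from exc

    # ---- stage: contingency + assignment + retention ---------------------
    stage = "assignment"
    try:
        table = build_contingency(mares)
        amap = assign_families(table)
        report = retention(mares, amap)
        freqs = haplotype_frequencies(table)
        cont = table.counts.reset_index()
        _write(cont, out_dir / "contingency.csv", outputs)
        _write(amap.to_frame(), out_dir / "assignment.csv", outputs)
        _write(report.per_mare, out_dir / "retention.csv", outputs)
        _write(freqs, out_dir / "frequencies.csv", outputs)
        summary["haplotype_counts"] = {
            h: int(c) for h, c in table.counts.sum(axis=0).items()
        }
        summary["assignment"] = {
            h: sorted(a.families) for h, a in amap.assignments.items()
        }
        summary["retained"] = report.retained
        summary["culled"] = report.culled
        summary["unassessable"] = report.unassessable
        if config.get("assignment", {}).get("oracle", False):
            _, optimum = matching_oracle(table)
            summary["oracle_optimum"] = optimum
    except NoDataError as exc:
        raise PipelineError(stage, exc) from exc
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # ---- stage: pedigree statistics (simulated pedigrees only) -----------
    if sim is not None:
        stage = "pedstats"
        try:
            replicates = int(config.get("pedstats", {}).get("replicates", 10_000))
            result = gene_origin_summary(
                sim.pedigree, replicates=replicates, seed=seed
            )
            _write(result.to_frame(), out_dir / "pedigree_summary.csv", outputs)
            summary["pedigree"] = {
                "f_e": result.f_e,
                "f_a": result.f_a,
                "n_g": result.n_g,
                "average_inbreeding": result.average_inbreeding,
                "completeness": result.completeness,
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, exc) from exc

    # ---- stage: MSY typing ------------------------------------------------
    stage = "msy"
    try:
        msy_cfg = config.get("msy", {})
        if "genotypes" in msy_cfg:
            df = io.read_msy_csv(msy_cfg["genotypes"])
            genos = [
                MsyGenotype(r["sample_id"], {l: r[l] for l in ("YE3", "YE17", "YXX")})
                for _, r in df.iterrows()
            ]
        elif mode == "simulate":
            df = emit_msy(sim.scenario.msy_proportions, msy_cfg.get("n", 10), seed=seed)
            genos = [
                MsyGenotype(r["sample_id"], {l: r[l] for l in ("YE3", "YE17", "YXX")})
                for _, r in df.iterrows()
            ]
        else:
            genos = ascal_stallions()
        calls = [(g.sample_id, call_msy(g)) for g in genos]
        call_df = pd.DataFrame(calls, columns=["sample_id", "haplotype"])
        freq_df = msy_frequencies([c for _, c in calls])
        _write(call_df, out_dir / "msy_calls.csv", outputs)
        _write(freq_df, out_dir / "msy_frequencies.csv", outputs)
        summary["msy"] = {
            row["haplotype"]: row["percent"] for _, row in freq_df.iterrows()
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    summary["outputs"] = outputs
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", out_dir / "summary.json")
    return summary
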