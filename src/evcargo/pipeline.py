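"""End-to-end orchestration: simulate -> align -> count -> enrich ->
profile -> gate, with a manifest recording config, seeds and checksums.

Stages communicate only through files in the output directory; rerunning
with the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .counting import count_genes, enrichment, ev_cell_ratio, family_table
from .cytometry import (
    DeathResult,
    GateConfig,
    compare_conditions,
    dose_response,
    gate,
    read_events,
)
from .fragment_profile import profile_gene
from .io import RunConfig, write_counts_tsv, write_tsv
from .synthetic_data import (
    CYTO_PRESETS,
    DOSE_RESPONSE_PRESET,
    CytoCondition,
    build_reference,
    default_profile,
    simulate_cytometry,
    simulate_library,
)
from .toy_aligner import align_library


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs were removed."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds derived from the run seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage; returns a manifest dict (also written as
    manifest.json).  On failure the partially written outputs of this run
    are removed and a stage-tagged :class:`StageError` is raised."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []

    def path(name: str) -> Path:
        p = out / name
        created.append(p)
        return p

    seeds = _child_seeds(config.seed, 2 + len(config.profiles) + len(config.cytometry_conditions))
    seed_log: dict[str, int] = {}
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": {},
    }

    stage = "setup"
    try:
        stage = "reference"
        ref_seed = seeds[0]
        seed_log["reference"] = ref_seed
        ref = build_reference(seed=ref_seed)
        ref.to_fasta(path("reference.fa"))
        ref.to_bed(path("genes.bed"))

        counts_by_profile = {}
        for i, name in enumerate(config.profiles):
            stage = f"simulate:{name}"
            lib_seed = seeds[2 + i]
            seed_log[f"library:{name}"] = lib_seed
            profile = default_profile(
                name, ref, read_count=config.n_reads, error_rate=config.error_rate
            )
            fastq = path(f"{name}.fastq")
            truth = path(f"{name}.truth.sam")
            simulate_library(profile, ref, fastq, truth, seed=lib_seed)

            stage = f"align:{name}"
            sam = path(f"{name}.sam")
            align_library(
                fastq, ref, sam,
                max_mismatches=config.max_mismatches, max_loci=config.max_loci,
            )

            stage = f"count:{name}"
            counts = count_genes(sam, ref.annotations, library_id=name)
            counts_by_profile[name] = counts
            write_counts_tsv(counts, path(f"{name}.counts.tsv"), ref.annotations)
            fam = family_table(counts, ref.annotations)
            write_tsv(fam.table, path(f"{name}.families.tsv"))

        stage = "enrich"
        pairs = {}
        for name in config.profiles:
            line, compartment = name.rsplit("_", 1)
            pairs.setdefault(line, {})[compartment] = counts_by_profile[name]
        enrich_rows = []
        for line, comp in sorted(pairs.items()):
            if "ev" in comp and "cell" in comp:
                fold = enrichment(comp["ev"], comp["cell"], "RNY5")
                ratios = ev_cell_ratio(comp["ev"], comp["cell"])
                enrich_rows.append(
                    {
                        "cell_line": line,
                        "gene_id": "RNY5",
                        "fold_enrichment": fold,
                        "ev_cell_ratio": ratios.get("RNY5", float("nan")),
                    }
                )
        if enrich_rows:
            import pandas as pd

            write_tsv(pd.DataFrame(enrich_rows), path("enrichment.tsv"))

        stage = "profile"
        for name in config.profiles:
            if not name.endswith("_ev"):
                continue
            prof = profile_gene(
                out / f"{name}.sam",
                ref.annotations,
                "RNY5",
                ref.pseudogene_set,
                policy=config.fragment_policy,
                threshold=config.fragment_threshold,
            )
            write_tsv(prof.to_frame(), path(f"{name}.rny5_profile.tsv"))

        stage = "cytometry"
        gcfg = GateConfig(config.hoechst_threshold, config.yopro_threshold)
        results: dict[str, DeathResult] = {}
        for j, cname in enumerate(config.cytometry_conditions):
            cseed = seeds[2 + len(config.profiles) + j] % (2**31 - 1)
            seed_log[f"cytometry:{cname}"] = cseed
            cond = CYTO_PRESETS[cname]
            cond = CytoCondition(**{**cond.__dict__, "event_count": config.cytometry_events})
            events_path = path(f"cyto_{cname}.tsv")
            simulate_cytometry(cond, seed=cseed, path=events_path)
            results[cname] = gate(read_events(events_path), gcfg, condition=cname)

        stage = "gate"
        import pandas as pd

        gate_rows = [
            {
                "condition": r.condition,
                "n_events": r.n_events,
                "n_hoechst_pos": r.n_hoechst_pos,
                "n_double_pos": r.n_double_pos,
                "percent_dead": r.percent_dead,
            }
            for r in results.values()
        ]
        write_tsv(pd.DataFrame(gate_rows), path("gating.tsv"))
        baseline = (
            "bj_untreated" if "bj_untreated" in results else next(iter(results))
        )
        write_tsv(compare_conditions(results, baseline), path("gating_vs_baseline.tsv"))

        dose_seed = seeds[1]
        seed_log["dose_response"] = dose_seed
        series = []
        for k, (dose, frac) in enumerate(DOSE_RESPONSE_PRESET):
            cond = CytoCondition(
                name=f"dose_{dose:g}", dead_fraction=frac,
                event_count=config.cytometry_events,
            )
            ev = simulate_cytometry(cond, seed=(dose_seed + k) % (2**31 - 1))
            series.append((dose, gate(ev, gcfg, condition=cond.name)))
        dose_df, monotone = dose_response(series)
        dose_df["monotone_flag"] = monotone
        write_tsv(dose_df, path("dose_response.tsv"))

        stage = "manifest"
        manifest["seeds"] = seed_log
        manifest["outputs"] = {
            p.name: _sha256(p) for p in sorted(created) if p.exists()
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:  # noqa: BLE001 - stage tagging is the contract
        for p in created:
            if p.exists():
                p.unlink()
        raise StageError(stage, exc) from exc
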