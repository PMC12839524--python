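"""End-to-end orchestration: simulate/load -> normalize -> DE -> comparisons.

A single structured config (YAML-friendly, schema-validated, unknown keys
rejected) drives all seven stages; every stage writes its outputs with content
hashes into a run manifest, stochastic stages record their derived sub-seeds,
and a stage failure marks the manifest and skips everything downstream.
Re-running the same config reproduces identical output hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from . import congruence as cong
from . import cross_species as cs
from . import diffexp as de
from . import enrichment as enr
from . import phylo_signal as ps
from .io import (
    SampleMetadata,
    read_counts,
    read_go,
    read_metadata,
    read_newick,
    read_orthogroups,
    write_newick,
)
from .normalize import (
    aggregate_to_orthogroups,
    compute_size_factors,
    normalize,
    restrict_to_core,
)
from .simulate import SimulationConfig, simulate_dataset, write_dataset

__all__ = ["PipelineConfig", "run_pipeline", "load_dataset_dir"]

log = logging.getLogger("phyloexpress")

STAGES = ["simulate", "aggregate", "de", "compare", "go", "congruence", "lambda"]


class InputPaths(BaseModel):
    model_config = ConfigDict(extra="forbid")
    counts: dict  # species_id -> TSV path
    metadata: str
    orthogroups: str
    tree: str
    go: str | None = None


class PipelineConfig(BaseModel):
    """Validated run configuration; exactly one of simulation/inputs is set."""

    model_config = ConfigDict(extra="forbid")

    outdir: str
    seed: int = 0
    simulation: dict | None = None  # keys of SimulationConfig
    inputs: InputPaths | None = None
    alpha_screen: float = 0.1  # raw-p screen (ANOVA effect fractions)
    alpha_de: float = 0.1  # BH threshold defining DE transcripts for GO
    top_k: int = 30
    n_null: int = 1000  # congruence randomization replicates
    mcmc: dict | None = None  # keys of MCMCSettings
    lambda_max_orthogroups: int | None = 500
    lambda_response: str = "wald"  # or "lfc"
    infinite_or_policy: str = "exclude"

    @field_validator("simulation")
    @classmethod
    def _sim_keys(cls, v):
        if v is not None:
            allowed = {f.name for f in dataclasses.fields(SimulationConfig)}
            unknown = set(v) - allowed
            if unknown:
                raise ValueError(f"unknown simulation keys {sorted(unknown)}")
        return v

    @field_validator("mcmc")
    @classmethod
    def _mcmc_keys(cls, v):
        if v is not None:
            allowed = {f.name for f in dataclasses.fields(ps.MCMCSettings)}
            unknown = set(v) - allowed
            if unknown:
                raise ValueError(f"unknown mcmc keys {sorted(unknown)}")
        return v

    def resolved(self):
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("set exactly one of 'simulation' or 'inputs'")
        if self.lambda_response not in ("wald", "lfc"):
            raise ValueError("lambda_response must be 'wald' or 'lfc'")
        return self


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    return int(
        np.random.SeedSequence([seed, STAGES.index(stage)]).generate_state(1)[0]
        % (2**31)
    )


def load_dataset_dir(indir) -> dict:
    """Load a dataset directory laid out as :func:`simulate.write_dataset` writes."""
    indir = Path(indir)
    counts = {}
    for p in sorted(indir.glob("counts_*.tsv")):
        sp = p.stem.removeprefix("counts_")
        counts[sp] = read_counts(p, sp)
    out = {
        "counts": counts,
        "metadata": read_metadata(indir / "metadata.tsv"),
        "og_map": read_orthogroups(indir / "orthogroups.tsv"),
        "tree": read_newick(indir / "species_tree.nwk"),
    }
    go_path = indir / "go_annotation.tsv"
    out["go"] = read_go(go_path) if go_path.exists() else None
    return out


def _load_inputs(paths: InputPaths) -> dict:
    counts = {sp: read_counts(p, sp) for sp, p in paths.counts.items()}
    return {
        "counts": counts,
        "metadata": read_metadata(paths.metadata),
        "og_map": read_orthogroups(paths.orthogroups),
        "tree": read_newick(paths.tree),
        "go": read_go(paths.go) if paths.go else None,
    }


# ---------------------------------------------------------------------------
# stages (each returns the objects downstream stages need and a {name: path})
# ---------------------------------------------------------------------------


def stage_aggregate(data: dict, outdir: Path) -> tuple:
    sfs, normalized = {}, {}
    for sp, tcm in data["counts"].items():
        sfs[sp] = compute_size_factors(tcm, allow_pseudo_reference=True)
        normalized[sp] = normalize(tcm, sfs[sp])
    ogem = aggregate_to_orthogroups(normalized, data["og_map"])
    core = restrict_to_core(ogem)
    log.info(
        "aggregate: %d orthogroups, %d core retained",
        len(ogem.values),
        len(core.values),
    )
    out = outdir / "orthogroup_expression.tsv"
    core.values.to_csv(out, sep="\t")
    sidecar = {
        "n_orthogroups_total": int(len(ogem.values)),
        "n_orthogroups_core": int(len(core.values)),
        "unassigned_fraction": ogem.unassigned_fraction.round(6).to_dict(),
        "size_factors": {
            sp: s.round(6).to_dict() for sp, s in sfs.items()
        },
    }
    side = outdir / "aggregate_summary.json"
    side.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    cnp = outdir / "copy_numbers.tsv"
    ogem.copy_numbers.to_csv(cnp, sep="\t")
    return (core, sfs), {
        "orthogroup_expression": out,
        "aggregate_summary": side,
        "copy_numbers": cnp,
    }


def stage_de(data: dict, outdir: Path) -> tuple:
    tables_tx = de.run_species_de(
        data["counts"], data["metadata"], level="transcript", log=log
    )
    tables_og = de.run_species_de(
        data["counts"],
        data["metadata"],
        data["og_map"],
        level="orthogroup",
        log=log,
    )
    paths = {}
    for level, tables in (("transcript", tables_tx), ("orthogroup", tables_og)):
        for sp, tab in tables.items():
            p = outdir / f"de_{level}_{sp}.tsv"
            tab.to_csv(p, sep="\t")
            paths[f"de_{level}_{sp}"] = p
    return (tables_tx, tables_og), paths


def stage_compare(core_ogem, tables_og, data, config, outdir: Path) -> tuple:
    anova = cs.og_anova(core_ogem.values, data["metadata"])
    scatter = cs.effect_size_scatter(anova, alpha_screen=config.alpha_screen)
    pairs = cs.pairwise_wald_correlations(tables_og)
    mean_r, t, p = cs.correlation_distribution_test(pairs)
    cn_corr = cs.copy_number_lfc_correlation(tables_og, data["og_map"])
    summary = {
        "effect_size_scatter": scatter,
        "wald_correlation": {"mean_r": mean_r, "t": t, "p": p},
        "copy_number_lfc_correlation": cn_corr,
    }
    pa = outdir / "effect_sizes.tsv"
    anova.to_csv(pa, sep="\t")
    pp = outdir / "pairwise_wald_correlations.tsv"
    pairs.to_csv(pp, sep="\t", index=False)
    pj = outdir / "compare_summary.json"
    pj.write_text(json.dumps(summary, indent=1, sort_keys=True, default=float))
    return (anova, pairs, summary), {
        "effect_sizes": pa,
        "pairwise_wald_correlations": pp,
        "compare_summary": pj,
    }


def stage_go(tables_tx, data, config, outdir: Path) -> tuple:
    if data["go"] is None:
        raise ValueError("GO stage requires a GO annotation input")
    enr_tables, paths = {}, {}
    for sp, tab in tables_tx.items():
        de_set = set(tab.index[(tab["padj"] < config.alpha_de).fillna(False)])
        universe = set(tab.index[tab["status"] == "ok"])
        enr_tables[sp] = enr.fisher_enrichment(de_set, data["go"], sp, universe)
        p = outdir / f"go_enrichment_{sp}.tsv"
        enr_tables[sp].to_csv(p, sep="\t")
        paths[f"go_enrichment_{sp}"] = p
    pairs = enr.pairwise_enrichment_correlations(
        enr_tables, infinite_or=config.infinite_or_policy
    )
    mean_r, t, p_val = cs.correlation_distribution_test(pairs)
    pp = outdir / "pairwise_go_correlations.tsv"
    pairs.to_csv(pp, sep="\t", index=False)
    pj = outdir / "go_summary.json"
    pj.write_text(
        json.dumps({"mean_r": mean_r, "t": t, "p": p_val}, indent=1, default=float)
    )
    paths.update({"pairwise_go_correlations": pp, "go_summary": pj})
    return (enr_tables, pairs), paths


def stage_congruence(tables_og, data, config, outdir: Path, seed: int) -> tuple:
    top = cong.top_de_orthogroups(tables_og, k=config.top_k)
    mat = pd.DataFrame({sp: tab["wald"] for sp, tab in tables_og.items()})
    profile = mat.loc[top].T.fillna(0.0)
    dendro = cong.cluster_species(profile)
    tree = data["tree"].restrict(dendro.leaf_labels)
    result = cong.icong_test(dendro, tree, n_null=config.n_null, seed=seed, log=log)
    pd_ = outdir / "expression_dendrogram.nwk"
    pd_.write_text(dendro.newick() + "\n")
    pt = outdir / "species_tree_used.nwk"
    write_newick(tree, pt)
    ph = outdir / "congruence_profile.tsv"
    profile.to_csv(ph, sep="\t")
    pj = outdir / "congruence.json"
    pj.write_text(json.dumps(result.as_dict(), indent=1))
    return (dendro, result), {
        "expression_dendrogram": pd_,
        "species_tree_used": pt,
        "congruence_profile": ph,
        "congruence": pj,
    }


def stage_lambda(tables_og, data, config, outdir: Path, seed: int) -> tuple:
    column = "wald" if config.lambda_response == "wald" else "lfc"
    Y = pd.DataFrame({sp: tab[column] for sp, tab in tables_og.items()})
    Y = Y[np.isfinite(Y).all(axis=1)]
    if config.lambda_max_orthogroups is not None and len(Y) > config.lambda_max_orthogroups:
        score = Y.abs().max(axis=1)
        keep = sorted(
            Y.index, key=lambda og: (-score[og], og)
        )[: config.lambda_max_orthogroups]
        Y = Y.loc[sorted(keep)]
    cov = ps.tree_to_covariance(data["tree"].restrict(list(Y.columns)))
    settings_kw = dict(config.mcmc or {})
    settings_kw["seed"] = seed
    settings = ps.MCMCSettings(**settings_kw)
    fits = ps.fit_lambda_gibbs_batch(Y, cov, settings)
    p = outdir / "lambda_fits.tsv"
    fits.to_csv(p, sep="\t")
    diag = {
        "n_orthogroups": int(len(fits)),
        "n_dropped_nonfinite": fits.attrs.get("n_dropped", 0),
        "n_diverged": int(fits["diverged"].sum()),
        "median_lambda": float(fits["lambda"].median()),
        "mean_ci_width": float((fits["ci_high"] - fits["ci_low"]).mean()),
        "fraction_reduced_model_preferred": float((fits["delta_dic"] < 0).mean()),
        "settings": dataclasses.asdict(settings),
    }
    pj = outdir / "lambda_diagnostics.json"
    pj.write_text(json.dumps(diag, indent=1, sort_keys=True))
    return fits, {"lambda_fits": p, "lambda_diagnostics": pj}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns (and writes) the manifest."""
    config = config.resolved()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": json.loads(config.model_dump_json()),
        "seed": config.seed,
        "stages": {},
    }

    def record(stage, paths, t0, seed=None):
        entry = {
            "status": "ok",
            "elapsed_s": round(time.time() - t0, 3),
            "outputs": {k: {"path": str(p), "sha256": _sha256(Path(p))}
                        for k, p in paths.items()},
        }
        if seed is not None:
            entry["derived_seed"] = seed
        manifest["stages"][stage] = entry

    def fail(stage, err):
        manifest["stages"][stage] = {"status": "failed", "error": str(err)}
        for later in STAGES[STAGES.index(stage) + 1 :]:
            manifest["stages"][later] = {"status": "skipped"}
        log.error("stage %s failed: %s", stage, err)

    done = False
    try:
        t0 = time.time()
        if config.simulation is not None:
            sim_kw = dict(config.simulation)
            sim_kw.setdefault("seed", _stage_seed(config.seed, "simulate"))
            ds = simulate_dataset(SimulationConfig(**sim_kw))
            data_dir = outdir / "dataset"
            paths = write_dataset(ds, data_dir)
            data = {
                "counts": ds.counts,
                "metadata": ds.metadata,
                "og_map": ds.og_map,
                "tree": ds.tree,
                "go": ds.go,
            }
            record(
                "simulate",
                {k: v for k, v in paths.items() if not v.endswith("truth")},
                t0,
                seed=sim_kw["seed"],
            )
        else:
            data = _load_inputs(config.inputs)
            record("simulate", {}, t0)

        t0 = time.time()
        (core, sfs), paths = stage_aggregate(data, outdir)
        record("aggregate", paths, t0)

        t0 = time.time()
        (tables_tx, tables_og), paths = stage_de(data, outdir)
        record("de", paths, t0)

        t0 = time.time()
        _, paths = stage_compare(core, tables_og, data, config, outdir)
        record("compare", paths, t0)

        t0 = time.time()
        if data["go"] is not None:
            _, paths = stage_go(tables_tx, data, config, outdir)
            record("go", paths, t0)
        else:
            manifest["stages"]["go"] = {"status": "skipped", "reason": "no GO input"}

        t0 = time.time()
        cseed = _stage_seed(config.seed, "congruence")
        _, paths = stage_congruence(tables_og, data, config, outdir, cseed)
        record("congruence", paths, t0, seed=cseed)

        t0 = time.time()
        lseed = _stage_seed(config.seed, "lambda")
        _, paths = stage_lambda(tables_og, data, config, outdir, lseed)
        record("lambda", paths, t0, seed=lseed)
        done = True
    except Exception as err:  # noqa: BLE001 - manifest must record the failure
        ran = [s for s in STAGES if s in manifest["stages"]]
        current = STAGES[len(ran)] if len(ran) < len(STAGES) else STAGES[-1]
        fail(current, err)

    manifest["completed"] = done
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest
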