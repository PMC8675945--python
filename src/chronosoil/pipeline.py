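"""End-to-end pipeline: configuration, stage orchestration, run manifest.

A run is described by a YAML (or dict) configuration naming the inputs,
the stages to run, the null-model replicate counts and a single top-level
seed.  The seed is split deterministically into fixed per-stage substreams
(via ``numpy.random.SeedSequence`` spawn keys), so enabling or disabling
one stage never changes another stage's draws.  Outputs are tabular TSV
plus a JSON manifest recording the seed and effective parameters.
Sample order in every output follows the input order.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly as asm
from . import community as comm
from . import enzymes as enz
from . import io as cio
from . import network as net
from . import simulate as sim

logger = logging.getLogger(__name__)

STAGES = ("simulate", "stoich", "diversity", "assembly", "network")

# fixed spawn keys: stage streams are independent of which stages run
_STAGE_KEYS = {name: i for i, name in enumerate(STAGES)}


class ConfigurationError(ValueError):
    pass


def stage_seed(seed: int | None, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage random substream of the top-level seed."""
    return np.random.SeedSequence(entropy=0 if seed is None else seed,
                                  spawn_key=(_STAGE_KEYS[stage],))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError("config must be a mapping")
    return config


def _require(config: dict, stage: str, *keys: str) -> None:
    inputs = config.get("inputs", {})
    missing = [k for k in keys if not inputs.get(k)]
    if missing:
        raise ConfigurationError(
            f"stage {stage!r} requires input(s) {missing} in config['inputs']"
        )


def run_pipeline(config: dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run the requested stages and write per-stage outputs plus a manifest.

    Returns the manifest dict.  All configuration problems (missing inputs
    for a requested stage, unknown stage names) are raised before any
    computation starts.
    """
    out_dir = Path(out_dir)
    stages = list(config.get("stages", []))
    params = dict(config.get("params", {}))
    seed = config.get("seed", seed)
    inputs = dict(config.get("inputs", {}))

    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigurationError(f"unknown stage(s) {unknown}; valid: {list(STAGES)}")

    # validate all requirements up front
    needs_table = [s for s in stages if s in ("diversity", "assembly", "network")]
    if needs_table and not (inputs.get("otu_table") or "simulate" in stages):
        raise ConfigurationError(
            f"stage(s) {needs_table} need an OTU table (input or simulate stage)"
        )
    if "assembly" in stages and not (inputs.get("tree") or "simulate" in stages):
        raise ConfigurationError("stage 'assembly' needs a tree (input or simulate stage)")
    if "stoich" in stages and not (inputs.get("enzymes") or "simulate" in stages):
        raise ConfigurationError("stage 'stoich' needs an enzyme table "
                                 "(input or simulate stage)")

    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "stages": stages, "params": params, "outputs": {}}

    table = tree = enzymes_df = metadata = None
    if inputs.get("otu_table"):
        table = cio.read_otu_table(inputs["otu_table"],
                                   inputs.get("orientation", "samples_in_rows"))
    if inputs.get("tree"):
        tree = cio.read_newick(inputs["tree"])
    if inputs.get("enzymes"):
        enzymes_df = cio.read_enzyme_table(inputs["enzymes"])
    if inputs.get("metadata"):
        metadata = cio.read_metadata(inputs["metadata"])

    if "simulate" in stages:
        ss = stage_seed(seed, "simulate")
        child = ss.spawn(4)
        n_otus = int(params.get("n_otus", 600))
        regime = sim.AssemblyRegime(
            mode=params.get("regime", "neutral"),
            n_samples=int(params.get("n_samples", 12)),
            n_otus=n_otus,
            depth=int(params.get("depth", sim.DEFAULT_DEPTH)),
            selection_strength=float(params.get("selection_strength", 0.5)),
        )
        tree = sim.simulate_tree(n_otus, seed=int(child[0].generate_state(1)[0] % 2**31))
        table, env = sim.simulate_communities(tree, regime, seed=child[1])
        enzymes_df = sim.simulate_enzymes(
            regime.n_samples,
            target_vector_angle=float(params.get("target_vector_angle", 55.0)),
            target_vector_length=float(params.get("target_vector_length", 1.3)),
            noise_sd=float(params.get("enzyme_noise_sd", 0.05)),
            seed=child[2],
        )
        cio.write_otu_table(table, out_dir / "otu_table.tsv")
        tree.write(str(out_dir / "tree.nwk"))
        enzymes_df.to_csv(out_dir / "enzymes.tsv", sep="\t", index_label="sample_id")
        env.to_frame().to_csv(out_dir / "environment.tsv", sep="\t",
                              index_label="sample_id")
        # emulate a chronosequence design: samples split evenly over the
        # four stand-age classes, with soil acidifying along stand age
        n = regime.n_samples
        classes = np.repeat(cio.AGE_CLASSES, -(-n // 4))[:n]
        sim_meta = pd.DataFrame(
            {"stand_age_class": classes,
             "pH": np.round(np.linspace(5.4, 4.2, n), 3)},
            index=table.index,
        )
        sim_meta.to_csv(out_dir / "metadata.tsv", sep="\t",
                        index_label="sample_id")
        if metadata is None:
            metadata = sim_meta
        truth = {"regime": regime.mode, "n_samples": regime.n_samples,
                 "n_otus": regime.n_otus, "depth": regime.depth}
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
        manifest["outputs"]["simulate"] = [
            "otu_table.tsv", "tree.nwk", "enzymes.tsv", "environment.tsv",
            "metadata.tsv", "truth.json",
        ]

    if "stoich" in stages:
        stoich = enz.stoichiometry_table(enzymes_df)
        stoich.to_csv(out_dir / "stoichiometry.tsv", sep="\t",
                      index_label="sample_id")
        manifest["outputs"]["stoich"] = ["stoichiometry.tsv"]

    if "diversity" in stages:
        ss = stage_seed(seed, "diversity")
        work = table
        depth = params.get("rarefy_depth")
        if depth:
            work = comm.rarefy(table, int(depth), seed=ss)
        alpha = comm.alpha_diversity(work)
        alpha.to_csv(out_dir / "alpha_diversity.tsv", sep="\t",
                     index_label="sample_id")
        bc = comm.bray_curtis(work)
        cio.write_distance_matrix(bc, out_dir / "bray_curtis.tsv")
        coords, eigvals, prop = comm.pcoa(bc)
        coords.to_csv(out_dir / "pcoa_coordinates.tsv", sep="\t",
                      index_label="sample_id")
        manifest["outputs"]["diversity"] = [
            "alpha_diversity.tsv", "bray_curtis.tsv", "pcoa_coordinates.tsv",
        ]

    if "assembly" in stages:
        ss = stage_seed(seed, "assembly")
        child = ss.spawn(2)
        n_null = int(params.get("n_null", 999))
        bnti_m = asm.bnti(table, tree, n_null=n_null, seed=child[0])
        rc_m = asm.raup_crick_bray(table, n_null=n_null, seed=child[1])
        bmntd_m = asm.bmntd(table, tree)
        pairs = asm.pairwise_assembly(bnti_m, rc_m, bmntd_m)
        cio.write_long_pairwise(pairs, out_dir / "assembly_pairs.tsv")
        if metadata is not None and "stand_age_class" in metadata.columns:
            groups = metadata.loc[table.index, "stand_age_class"]
            fr = asm.process_fractions(pairs, groups)
            fr.to_csv(out_dir / "process_fractions.tsv", sep="\t")
            manifest["outputs"].setdefault("assembly", []).append(
                "process_fractions.tsv")
        manifest["outputs"].setdefault("assembly", []).append("assembly_pairs.tsv")

    if "network" in stages:
        ss = stage_seed(seed, "network")
        # co-occurrence estimation on the most abundant taxa: rare taxa
        # carry almost no correlation information at survey depths and
        # would dominate the basis-variance system's cost
        top = int(params.get("network_top_otus", 100))
        keep = table.sum(axis=0).nlargest(min(top, table.shape[1])).index
        net_table = table[keep]
        corr, pvals = net.sparcc(
            net_table,
            n_inner_iter=int(params.get("sparcc_inner", 20)),
            n_bootstrap=int(params.get("sparcc_bootstrap", 100)),
            seed=ss,
        )
        threshold = params.get("correlation_threshold")
        if threshold is None:
            try:
                threshold, _scan = net.rmt_threshold(corr)
            except ValueError:
                threshold = 0.6
                logger.warning("RMT scan found no Poisson transition; "
                               "falling back to cutoff %.2f", threshold)
        g = net.build_network(corr, pvals, float(threshold),
                              alpha=float(params.get("alpha", 0.05)))
        net.write_edge_list(g, out_dir / "network_edges.tsv")
        modules, modularity = net.detect_modules(g)
        roles = net.zi_pi(g, modules)
        roles.to_csv(out_dir / "node_roles.tsv", sep="\t")
        topo = net.topology(g).as_dict()
        topo["modularity"] = modularity
        topo["threshold"] = float(threshold)
        topo = {k: (None if isinstance(v, float) and np.isnan(v) else v)
                for k, v in topo.items()}
        (out_dir / "network_topology.json").write_text(json.dumps(topo, indent=2))
        manifest["outputs"]["network"] = [
            "network_edges.tsv", "node_roles.tsv", "network_topology.json",
        ]

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
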