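"""End-to-end pipeline orchestration with a reproducibility manifest.

Stage order: simulate/load -> qc -> structure -> sharing -> assoc ->
project.  Every numeric output file carries a provenance header
(stage, parameters, seed) as '#'-prefixed lines, and the manifest records
dataset sizes after each filter, all parameters, and a SHA-256 checksum of
every output so a rerun with the same config and seed is verifiably
identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import ibd as ibd_mod
from . import projection as proj_mod
from . import qc as qc_mod
from . import simulate as sim_mod
from . import structure as struct_mod
from .core import allele_frequencies, read_plink_text

log = logging.getLogger("caprascape")


class PipelineDependencyError(RuntimeError):
    pass


class StageError(RuntimeError):
    pass


DEFAULT_STAGES = ("simulate", "qc", "structure", "sharing", "assoc", "project")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, seed: int,
               params: dict | None = None, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage: {stage}\n# seed: {seed}\n")
        if params:
            fh.write(f"# params: {json.dumps(params, default=str)}\n")
        df.to_csv(fh, sep="\t", index=index)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(cfg: dict, outdir: str | Path) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", list(DEFAULT_STAGES))
    manifest: dict = {"seed": seed, "stages": {}, "outputs": {},
                      "config": {k: v for k, v in cfg.items() if k != "simulate"}}
    state: dict = {}

    def record(stage: str, info: dict, outputs: dict[str, Path]) -> None:
        manifest["stages"][stage] = info
        for name, p in outputs.items():
            manifest["outputs"][f"{stage}/{name}"] = {
                "path": str(p), "sha256": _sha256(Path(p))}

    try:
        if "simulate" in stages:
            sim_cfg = sim_mod.SimulationConfig(**cfg.get("simulate", {}), seed=seed) \
                if "seed" not in cfg.get("simulate", {}) \
                else sim_mod.SimulationConfig(**cfg["simulate"])
            ds = sim_mod.simulate_dataset(sim_cfg)
            paths = sim_mod.write_dataset(ds, outdir / "simulated")
            state["genotypes"] = ds.genotypes
            state["env"] = ds.env
            state["truth"] = ds.truth
            record("simulate", {"n_individuals": ds.genotypes.n_individuals,
                                "n_snps": ds.genotypes.n_snps}, paths)
            log.info("simulate: %d individuals x %d SNPs",
                     ds.genotypes.n_individuals, ds.genotypes.n_snps)
        else:
            inputs = cfg["inputs"]
            state["genotypes"] = read_plink_text(inputs["ped"], inputs["map"])
            state["env"] = pd.read_csv(inputs["env"], sep="\t", comment="#")
            record("load", {"n_individuals": state["genotypes"].n_individuals,
                            "n_snps": state["genotypes"].n_snps}, {})

        if "qc" in stages:
            params = qc_mod.QCParams(**cfg.get("qc", {}))
            sets = qc_mod.build_datasets(state["genotypes"], params, seed=seed)
            state["datasets"] = sets
            rep_path = outdir / "qc_report.tsv"
            _write_tsv(sets["report"], rep_path, "qc", seed, params.__dict__)
            counts_path = outdir / "qc_counts.tsv"
            _write_tsv(sets["counts"], counts_path, "qc", seed)
            for _, row in sets["counts"].iterrows():
                log.info("qc %-14s: %4d individuals, %5d SNPs",
                         row["stage"], row["n_individuals"], row["n_snps"])
            record("qc", {s: {"n_individuals": sets[s].n_individuals,
                              "n_snps": sets[s].n_snps}
                          for s in ("haplotype", "structure", "landscape")},
                   {"report": rep_path, "counts": counts_path})

        if "structure" in stages:
            if "datasets" not in state:
                raise PipelineDependencyError("structure stage requires qc output")
            g = state["datasets"]["structure"]
            d = struct_mod.ibs_distance(g)
            mds = struct_mod.classical_mds(d, k=int(cfg.get("structure", {}).get("k", 2)))
            mds_path = outdir / "mds_coordinates.tsv"
            _write_tsv(pd.DataFrame(mds.coordinates,
                                    index=mds.labels,
                                    columns=[f"C{i+1}" for i in range(mds.coordinates.shape[1])]),
                       mds_path, "structure", seed, index=True)
            freqs = allele_frequencies(g)
            rey = struct_mod.reynolds_matrix(freqs)
            phy_path = outdir / "reynolds.phylip"
            rey.to_phylip(phy_path)
            outputs = {"mds": mds_path, "reynolds": phy_path}
            if len(rey.labels) >= 3:
                tree = struct_mod.nj_bootstrap_tree(
                    g, n_boot=int(cfg.get("structure", {}).get("n_boot", 100)),
                    seed=seed, outgroup=cfg.get("structure", {}).get("outgroup"))
                tree_path = outdir / "nj_consensus.nwk"
                tree.write_newick(tree_path)
                outputs["tree"] = tree_path
            record("structure", {"n_individuals": g.n_individuals,
                                 "mds_axes": mds.coordinates.shape[1]}, outputs)

        if "sharing" in stages:
            if "datasets" not in state:
                raise PipelineDependencyError("sharing stage requires qc output")
            g = state["datasets"]["haplotype"]
            if cfg.get("inputs", {}).get("ibd_segments"):
                segs = ibd_mod.IBDSegmentSet.read_refinedibd(cfg["inputs"]["ibd_segments"])
            else:
                full = state["genotypes"]
                keep = set(g.sample_ids)
                idx = [i for i, s in enumerate(full.sample_ids) if s in keep]
                segs = ibd_mod.detect_ibd_naive(
                    full.take_individuals(idx),
                    min_len_bp=int(cfg.get("sharing", {}).get("min_len_bp", 200_000)))
            share = ibd_mod.breed_sharing_matrix(segs, g)
            share_path = outdir / "haplotype_sharing.tsv"
            links_path = outdir / "haplotype_sharing_links.tsv"
            share.write_tsv(share_path)
            share.write_circos_links(links_path)
            state["sharing"] = share
            record("sharing", {"n_segments": len(segs)},
                   {"matrix": share_path, "links": links_path})

        if "assoc" in stages:
            if "datasets" not in state:
                raise PipelineDependencyError("assoc stage requires qc output")
            g = state["datasets"]["landscape"]
            env_ind = assoc_mod.env_for_individuals(state["env"], g)
            covs = assoc_mod.structure_pca(g, k=cfg.get("assoc", {}).get("k", "auto"))
            results = assoc_mod.run_association(
                g, env_ind, covs,
                min_count=int(cfg.get("assoc", {}).get("min_count", 5)))
            gene_bed = cfg.get("inputs", {}).get("genes")
            if gene_bed:
                results = assoc_mod.annotate_hits(
                    results, assoc_mod.read_gene_bed(gene_bed), g)
            state["assoc"] = results
            state["assoc_panel"] = g
            res_path = outdir / "association_results.tsv"
            _write_tsv(results, res_path, "assoc", seed,
                       {"k": covs.k, "method": covs.method})
            n_sig = int((results["q_value"] < 0.05).sum()) if len(results) else 0
            log.info("assoc: %d tests, %d significant at q<0.05", len(results), n_sig)
            record("assoc", {"n_tests": len(results), "n_significant": n_sig,
                             "k_pcs": covs.k}, {"results": res_path})

        if "project" in stages:
            if "assoc" not in state:
                raise PipelineDependencyError(
                    "projection requires association output; enable the assoc stage")
            results = state["assoc"]
            hits = results[results["q_value"] < float(
                cfg.get("project", {}).get("fdr", 0.05))]
            g = state["assoc_panel"]
            freqs = allele_frequencies(g).freq
            kop_path = cfg.get("inputs", {}).get("koppen")
            kop = proj_mod.load_koppen_table(kop_path) if kop_path else None
            # synthetic breeds need a classification; map by latitude rank when
            # no table is supplied and breeds are not in the bundled reference
            if kop is None:
                ref = proj_mod.load_koppen_table()
                breeds = sorted(set(g.breed_codes))
                if not set(breeds) <= set(ref["breed_code"]):
                    half = len(breeds) // 2
                    kop = pd.DataFrame({
                        "breed_code": breeds,
                        "current_class": ["Dfb"] * half + ["Csa"] * (len(breeds) - half),
                        "future_class": ["Cfa"] * half + ["BSh"] * (len(breeds) - half),
                    })
                else:
                    kop = ref
            table = proj_mod.run_projection(hits, freqs, state["env"], kop,
                                            grouping=cfg.get("project", {}).get("grouping", "dry"))
            proj_path = outdir / "projection.tsv"
            _write_tsv(table, proj_path, "project", seed)
            record("project", {"n_projected": len(table)}, {"table": proj_path})
    except (PipelineDependencyError,):
        raise
    except Exception as exc:  # halt with stage attribution; keep partial outputs
        done = list(manifest["stages"])
        raise StageError(
            f"pipeline failed after stages {done}: {type(exc).__name__}: {exc}"
        ) from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
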