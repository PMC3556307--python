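"""End-to-end pipeline: mask -> match -> merge -> cluster -> characterize.

One config object drives every stage; all randomness flows from a
single seed through named sub-streams, so a rerun with the same config
and seed is bit-identical (the manifest records per-stage counts and
output checksums to make that checkable).
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import yaml

from . import clustering, enrichment, masking, mems, motif, simulate, ucr
from ._seeds import stage_seed
from .io import Genome

logger = logging.getLogger("ultracons")


@dataclasses.dataclass
class PipelineConfig:
    species: dict  # species_id -> {"fasta": path} or simulate block
    min_lengths: tuple[int, ...] = (50,)
    flank: int = 50
    window: int = 100_000
    min_genes: int = 10
    inflation: float = 2.0
    max_e: float = 1e-5
    k_embed: int = 5
    k_motif: int = 8
    bg_length: int = 10_000
    report_threshold: float = 1e-4
    seed: int = 0
    outdir: str = "ultracons_out"

    def __post_init__(self):
        if len(self.species) < 2:
            raise ValueError("pipeline needs at least 2 species")
        for v in (self.flank, self.window, self.inflation, self.k_embed,
                  self.k_motif, self.bg_length):
            if v <= 0:
                raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_or_simulate(config: PipelineConfig) -> tuple[dict[str, Genome], dict]:
    genomes: dict[str, Genome] = {}
    truth_info: dict = {}
    sim_specs = {
        sp: blk for sp, blk in config.species.items() if "simulate" in blk
    }
    for sp, blk in config.species.items():
        if "fasta" in blk:
            genomes[sp] = Genome.from_fasta(blk["fasta"], species=sp)
    if sim_specs:
        specs = {
            sp: simulate.SpeciesSpec(
                species_id=sp,
                n_scaffolds=blk["simulate"].get("n_scaffolds", 1),
                scaffold_length=blk["simulate"]["scaffold_length"],
                gc_content=blk["simulate"].get("gc_content", 0.5),
            )
            for sp, blk in sim_specs.items()
        }
        for sp, spec in specs.items():
            genomes[sp] = simulate.generate_genome(spec, config.seed)
        plants = []
        for sp, blk in sim_specs.items():
            for p in blk["simulate"].get("plants", []):
                plants.append(simulate.PlantSpec(**p))
        if plants:
            # plants listed under any species apply globally; dedupe by id
            unique = {p.element_id: p for p in plants}
            genomes, truth = simulate.plant_elements(
                genomes, list(unique.values()), config.seed
            )
            truth_info["n_planted"] = len(unique)
    return genomes, truth_info


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "checksums": {}}
    t0 = time.time()

    genomes, truth_info = _load_or_simulate(config)
    manifest["stages"]["input"] = {
        "species": sorted(genomes),
        **truth_info,
    }

    masked: dict[str, Genome] = {}
    for sp, genome in sorted(genomes.items()):
        logger.info("masking %s", sp)
        masked[sp], intervals = masking.mask_genome(genome)
        manifest["stages"].setdefault("mask", {})[sp] = len(intervals)

    pairs = list(itertools.combinations(sorted(masked), 2))
    manifest["stages"]["pair_comparisons"] = len(pairs)

    for min_len in config.min_lengths:
        track = f"minlen{min_len}"
        pair_matches: dict[tuple[str, str], list[mems.MatchRecord]] = {}
        for a, b in pairs:
            logger.info("matching %s vs %s at >= %d bp", a, b, min_len)
            found = mems.find_mems(masked[a], masked[b], min_len)
            found = mems.remask_matches(found, masked[a], min_len)
            pair_matches[(a, b)] = found
        n_matches = sum(len(v) for v in pair_matches.values())

        all_ucrs: list[ucr.UCR] = []
        for sp in sorted(masked):
            intervals = ucr.project_matches(pair_matches, sp)
            all_ucrs.extend(
                ucr.merge_to_ucrs(intervals, genomes[sp], flank=config.flank)
            )
        bed, df = ucr.ucrs_to_tables(all_ucrs)
        ucr_path = outdir / f"ucrs_{track}.tsv"
        df.to_csv(ucr_path, sep="\t", index=False)
        manifest["checksums"][ucr_path.name] = _checksum(ucr_path)
        manifest["stages"][track] = {
            "matches": n_matches,
            "ucrs": len(all_ucrs),
            "per_species": {
                sp: sum(1 for u in all_ucrs if u.species == sp)
                for sp in sorted(masked)
            },
        }

        if len(all_ucrs) >= 2 and min_len == max(config.min_lengths):
            sequences = {u.ucr_id: u.sequence_with_flanks for u in all_ucrs}
            species_of = {u.ucr_id: u.species for u in all_ucrs}
            graph = clustering.build_graph(sequences, max_e=config.max_e)
            clusters = clustering.mcl(
                graph, inflation=config.inflation, species_of=species_of
            )
            manifest["stages"][track]["clusters"] = len(clusters)
            manifest["stages"][track]["cluster_sizes"] = sorted(
                (c.size for c in clusters), reverse=True
            )
            cl_path = outdir / f"clusters_{track}.tsv"
            with open(cl_path, "w") as fh:
                fh.write("ucr_id\tcluster_id\n")
                for c in clusters:
                    for m in c.member_ids:
                        fh.write(f"{m}\t{c.cluster_id}\n")
            manifest["checksums"][cl_path.name] = _checksum(cl_path)

            profiles = [
                clustering.kmer_profile(sequences[i], k=config.k_embed)
                for i in sorted(sequences)
            ]
            import numpy as np

            emb = clustering.mce_embed(
                np.array(profiles), d=min(3, len(profiles)),
                ids=sorted(sequences),
            )
            emb_path = outdir / f"embedding_{track}.tsv"
            with open(emb_path, "w") as fh:
                dims = "\t".join(f"dim{i+1}" for i in range(emb.coordinates.shape[1]))
                fh.write(f"ucr_id\t{dims}\n")
                for uid, row in zip(emb.ids, emb.coordinates):
                    fh.write(uid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
            manifest["checksums"][emb_path.name] = _checksum(emb_path)

            # motif stage: consensus + proportional background per cluster
            ucr_by_id = {u.ucr_id: u for u in all_ucrs}
            motif_rows = []
            for c in clusters:
                if c.size < 2:
                    continue
                seqs = [sequences[m] for m in c.member_ids]
                rep = motif.consensus_sequence(seqs)
                if len(rep) < config.k_motif:
                    continue
                total = sum(c.species_composition.values())
                fractions = {
                    sp: n / total for sp, n in c.species_composition.items()
                }
                bg = motif.build_background(
                    fractions,
                    masked,
                    motif.BackgroundSpec(
                        total_length=config.bg_length,
                        seed=stage_seed(config.seed, f"bg:{c.cluster_id}"),
                    ),
                )
                motif_rows.append(
                    motif.oligomer_enrichment(
                        rep, bg, k=config.k_motif,
                        report_threshold=config.report_threshold,
                        cluster_id=c.cluster_id,
                    )
                )
            if motif_rows:
                import pandas as pd

                motif_df = pd.concat(motif_rows, ignore_index=True)
                motif_path = outdir / f"motifs_{track}.tsv"
                motif_df.to_csv(motif_path, sep="\t", index=False)
                manifest["checksums"][motif_path.name] = _checksum(motif_path)
                manifest["stages"][track]["flagged_oligomers"] = int(
                    motif_df.flagged.sum()
                )

    manifest["runtime_s"] = round(time.time() - t0, 2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
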