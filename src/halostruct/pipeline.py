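"""Workflow orchestration from a single TOML config.

Runs the enabled stages (superpositions, composition deltas, surface
statistics, ligand transfer, phylogeny) and writes one TSV per analysis
plus a combined structure-comparison table and a structured log.  All
randomness is seeded from the config; two runs with identical config
produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .composition import composition_delta, composition_report
from .fasta import read_fasta
from .ligand_transfer import (
    detect_clashes,
    measure_distance,
    transplant_ligand,
    truncate_gsh_to_gec,
)
from .phylo import bootstrap_support, read_alignment, write_newick
from .structure_io import missing_residues, read_structure
from .superpose import superpose_dimer, superpose_monomer
from .surface import charge_evenness, coulomb_surface, shrake_rupley, surface_residues

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "validate_config", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    # superposition
    superpose: bool = False
    target_pdb: str | None = None
    target_chains: str = "A,B"
    references: list[str] = field(default_factory=list)  # "path=chainA,chainB"
    cycles: int = 5
    reject_factor: float = 2.0
    # composition
    composition: bool = False
    query_fasta: str | None = None
    reference_fasta: str | None = None
    # surface
    surface: bool = False
    probe_radius: float = 1.4
    n_points: int = 960
    n_perm: int = 999
    rel_threshold: float = 0.25
    # ligand transfer
    ligand: bool = False
    ligand_ref_pdb: str | None = None
    ligand_resname: str = "GSH"
    truncate: bool = True
    clash_tolerance: float = 0.4
    # phylogeny
    phylo: bool = False
    msa_path: str | None = None
    boot_reps: int = 1000
    boot_threshold: float = 40.0

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _reference_specs(config: RunConfig) -> list[tuple[str, tuple[str, str]]]:
    out = []
    for spec in config.references:
        path, _, chains = spec.partition("=")
        chain_pair = tuple((chains or "A,B").split(","))
        out.append((path, chain_pair))
    return out


def validate_config(config: RunConfig) -> list[str]:
    """Collect problems (missing files, bad chains); empty list = runnable."""
    problems: list[str] = []

    def check_file(path: str | None, what: str) -> None:
        if path is None:
            problems.append(f"{what}: no path configured")
        elif not Path(path).exists():
            problems.append(f"{what}: file not found: {path}")

    if config.superpose:
        check_file(config.target_pdb, "superpose target")
        if config.target_pdb and Path(config.target_pdb).exists():
            target = read_structure(Path(config.target_pdb))
            for cid in config.target_chains.split(","):
                if cid not in target.chain_ids:
                    problems.append(
                        f"chain {cid!r} absent from target entry {target.id}"
                    )
        for path, chains in _reference_specs(config):
            check_file(path, "superpose reference")
            if Path(path).exists():
                ref = read_structure(Path(path))
                for cid in chains:
                    if cid not in ref.chain_ids:
                        problems.append(f"chain {cid!r} absent from entry {ref.id}")
    if config.composition:
        check_file(config.query_fasta, "composition query")
        check_file(config.reference_fasta, "composition reference")
    if config.surface:
        check_file(config.target_pdb, "surface target")
    if config.ligand:
        check_file(config.target_pdb, "ligand target")
        check_file(config.ligand_ref_pdb, "ligand reference")
    if config.phylo:
        check_file(config.msa_path, "phylogeny MSA")
    return problems


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run all enabled stages; returns {stage/table name: output path}."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    log: dict[str, object] = {"version": __version__, "seed": config.seed, "stages": {}}

    def record(stage: str, status: str, **extra) -> None:
        log["stages"][stage] = {"status": status, **extra}

    problems = validate_config(config)
    if problems:
        raise StageError("validate", ValueError("; ".join(problems)))

    if config.superpose:
        try:
            target = read_structure(Path(config.target_pdb))
            t_chains = tuple(config.target_chains.split(","))
            rows = []
            for path, chains in _reference_specs(config):
                ref = read_structure(Path(path))
                mono = superpose_monomer(
                    target, t_chains[0], ref, chains[0],
                    cycles=config.cycles, reject_factor=config.reject_factor,
                )
                row = {
                    "entry": ref.id,
                    "rmsd_monomer": round(mono.rmsd, 2),
                    "n_aligned": mono.n_aligned,
                    "rmsd_dimer": "",
                    "n_aligned_dimer": "",
                    "identity_pct": round(mono.identity_percent, 2),
                }
                if len(t_chains) == 2 and len(chains) == 2:
                    dim = superpose_dimer(
                        target, t_chains, ref, chains,
                        cycles=config.cycles, reject_factor=config.reject_factor,
                    )
                    row["rmsd_dimer"] = round(dim.rmsd, 2)
                    row["n_aligned_dimer"] = dim.n_aligned
                rows.append(row)
            table = pd.DataFrame(rows)
            path = out_dir / "structure_comparison.tsv"
            table.to_csv(path, sep="\t", index=False)
            outputs["structure_comparison"] = path
            # missing-residue bookkeeping for the target entry
            gap_rows = []
            for chain in target.chains:
                if not chain.seqres:
                    continue
                for seg in missing_residues(chain):
                    gap_rows.append(
                        {
                            "chain": chain.chain_id,
                            "start": seg.start,
                            "end": seg.end,
                            "length": seg.length,
                            "location": seg.location,
                        }
                    )
            if gap_rows:
                gpath = out_dir / "missing_residues.tsv"
                pd.DataFrame(gap_rows).to_csv(gpath, sep="\t", index=False)
                outputs["missing_residues"] = gpath
            record("superpose", "ok", references=len(rows))
        except StageError:
            raise
        except Exception as exc:
            record("superpose", "failed", error=str(exc))
            _write_log(out_dir, log)
            raise StageError("superpose", exc) from exc
    else:
        record("superpose", "skipped", reason="toggle off")

    if config.composition:
        try:
            query = read_fasta(config.query_fasta)
            ref = read_fasta(config.reference_fasta)
            qid, qseq = next(iter(query.items()))
            rid, rseq = next(iter(ref.items()))
            delta = composition_delta(qseq, rseq, qid, rid)
            report = composition_report([delta])
            path = out_dir / "composition_delta.tsv"
            report.to_csv(path, sep="\t")
            outputs["composition_delta"] = path
            record("composition", "ok", query=qid, reference=rid)
        except Exception as exc:
            record("composition", "failed", error=str(exc))
            _write_log(out_dir, log)
            raise StageError("composition", exc) from exc
    else:
        record("composition", "skipped", reason="toggle off")

    if config.surface:
        try:
            target = read_structure(Path(config.target_pdb))
            sasa = shrake_rupley(target, config.probe_radius, config.n_points)
            surf = surface_residues(sasa, config.rel_threshold)
            scores = coulomb_surface(target, sasa, config.rel_threshold)
            rows = []
            for rid, area in sorted(sasa.per_residue.items()):
                rows.append(
                    {
                        "chain": rid[0],
                        "resseq": rid[1],
                        "icode": rid[2],
                        "resname": sasa.resnames[rid],
                        "sasa": round(area, 2),
                        "rel_sasa": round(sasa.relative[rid], 4),
                        "surface": rid in surf,
                        "coulomb_score": round(scores.get(rid, 0.0), 4),
                    }
                )
            path = out_dir / "surface.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            outputs["surface"] = path
            evenness = charge_evenness(
                target, sasa, n_perm=config.n_perm, seed=config.seed,
                rel_threshold=config.rel_threshold,
            )
            epath = out_dir / "charge_evenness.tsv"
            pd.DataFrame(
                [
                    {
                        "statistic_A": round(evenness.statistic, 4),
                        "p_clustered": evenness.p_clustered,
                        "n_charged_surface": evenness.n_charged_surface,
                        "n_perm": config.n_perm,
                        "seed": config.seed,
                    }
                ]
            ).to_csv(epath, sep="\t", index=False)
            outputs["charge_evenness"] = epath
            record("surface", "ok")
        except Exception as exc:
            record("surface", "failed", error=str(exc))
            _write_log(out_dir, log)
            raise StageError("surface", exc) from exc
    else:
        record("surface", "skipped", reason="toggle off")

    if config.ligand:
        try:
            target = read_structure(Path(config.target_pdb))
            ref = read_structure(Path(config.ligand_ref_pdb))
            t_chain = config.target_chains.split(",")[0]
            sup = superpose_monomer(
                target, t_chain, ref, ref.chain_ids[0],
                cycles=config.cycles, reject_factor=config.reject_factor,
            )
            lig = transplant_ligand(target, ref, config.ligand_resname, sup)
            if config.truncate:
                lig = truncate_gsh_to_gec(lig)
            clashes = detect_clashes(lig, target, config.clash_tolerance)
            path = out_dir / "ligand_clashes.tsv"
            pd.DataFrame([c.__dict__ for c in clashes]).to_csv(
                path, sep="\t", index=False
            )
            outputs["ligand_clashes"] = path
            record(
                "ligand", "ok",
                source=lig.source_entry, edits=lig.edits, clashes=len(clashes),
            )
        except Exception as exc:
            record("ligand", "failed", error=str(exc))
            _write_log(out_dir, log)
            raise StageError("ligand", exc) from exc
    else:
        record("ligand", "skipped", reason="toggle off")

    if config.phylo:
        try:
            msa = read_alignment(config.msa_path)
            tree = bootstrap_support(
                msa, n_reps=config.boot_reps, seed=config.seed,
                threshold=config.boot_threshold,
            )
            path = out_dir / "tree.nwk"
            path.write_text(write_newick(tree) + "\n")
            outputs["tree"] = path
            dpath = out_dir / "tree_display.nwk"
            dpath.write_text(write_newick(tree, apply_threshold=True) + "\n")
            outputs["tree_display"] = dpath
            record("phylo", "ok", n_taxa=len(msa), boot_reps=config.boot_reps)
        except Exception as exc:
            record("phylo", "failed", error=str(exc))
            _write_log(out_dir, log)
            raise StageError("phylo", exc) from exc
    else:
        record("phylo", "skipped", reason="toggle off")

    _write_log(out_dir, log)
    outputs["log"] = out_dir / "run_log.json"
    return outputs


def _write_log(out_dir: Path, log: dict) -> None:
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
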