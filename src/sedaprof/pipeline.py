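"""End-to-end orchestration: simulate → filter → align → assign → profile
→ damage → ordination → correlation → consensus, from one declarative
config, with deterministic seeding and a JSON manifest of every stage's
counts.

Filter defaults are the pipeline's published operating point: minimum
read length 25 nt, DUST score ≤ 1, edit distance ≤ 5% of read length,
damage reported at ≥ 500 supporting reads.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import align as al
from . import assign as asg
from . import damage as dmg
from . import preprocess as pp
from . import profiles as prof
from . import simulate as sim
from . import stats as st
from .consensus import pileup_consensus
from .taxonomy import TaxonomyTree

__all__ = ["FilterParams", "LibrarySpec", "PipelineConfig", "run", "load_config"]


@dataclass
class FilterParams:
    min_len: int = 25
    dust_max: float = 1.0
    edit_frac: float = 0.05
    damage_min_reads: int = 500


@dataclass
class LibrarySpec:
    library_id: str
    site: str
    layer: str
    n_reads: int
    mixture: dict[str, float]  # species name → proportion
    culture: str = ""
    library_type: str = "sediment"
    damage_d1: float = 0.0
    damage_decay: float = 0.3
    seq_error: float = 0.001
    dup_frac: float = 0.0
    lowcomplex_frac: float = 0.0
    frag_len_mean: float = 60.0
    frag_len_sd: float = 15.0


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "sedaprof_out"
    panel_seq_len: int = 1000
    filters: FilterParams = field(default_factory=FilterParams)
    libraries: list[LibrarySpec] = field(default_factory=list)
    consensus_taxon: str | None = None
    nmds_restarts: int = 20
    biomass: dict[str, float] = field(default_factory=dict)


def load_config(path: str | Path) -> PipelineConfig:
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    filters = FilterParams(**raw.pop("filters", {}))
    libraries = [LibrarySpec(**lib) for lib in raw.pop("libraries", [])]
    return PipelineConfig(filters=filters, libraries=libraries, **raw)


def _mixture_by_taxid(
    tree: TaxonomyTree, mixture: Mapping[str, float]
) -> dict[int, float]:
    return {tree.find_name(name): p for name, p in mixture.items()}


def run(config: PipelineConfig, write: bool = True) -> dict[str, Any]:
    """Execute every stage; return (and optionally write) the manifest.

    Rerunning with the same config reproduces the outputs byte for byte:
    all randomness flows from config.seed and per-library offsets of it.
    """
    out = Path(config.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    tree = sim.make_toy_taxonomy()
    panel_fasta, acc_map = sim.make_reference_panel(
        tree, seq_len=config.panel_seq_len, seed=config.seed
    )
    panel = sim.parse_fasta(panel_fasta)

    manifest: dict[str, Any] = {
        "seed": config.seed,
        "filters": dataclasses.asdict(config.filters),
        "panel": {"n_references": len(panel), "seq_len": config.panel_seq_len},
        "libraries": {},
    }

    per_library_assignments: dict[str, list[asg.ReadAssignment]] = {}
    metas: list[prof.LibraryMeta] = []
    chosen_hits_by_library: dict[str, dict[str, al.AlignmentHit]] = {}
    reads_by_library: dict[str, dict[str, pp.Read]] = {}

    for i, spec in enumerate(config.libraries):
        stage = f"simulate[{spec.library_id}]"
        try:
            cfg = sim.SimConfig(
                seed=(config.seed + 1009 * (i + 1)) % (2**31),
                n_reads=spec.n_reads,
                mixture=_mixture_by_taxid(tree, spec.mixture),
                frag_len_mean=spec.frag_len_mean,
                frag_len_sd=spec.frag_len_sd,
                damage_d1=spec.damage_d1,
                damage_decay=spec.damage_decay,
                seq_error=spec.seq_error,
                dup_frac=spec.dup_frac,
                lowcomplex_frac=spec.lowcomplex_frac,
            )
            fastq, truth = sim.simulate_library(cfg, panel_fasta, acc_map)
            reads = pp.reads_from_fastq(fastq)

            stage = f"preprocess[{spec.library_id}]"
            clean, report = pp.run_filters(
                reads,
                min_len=config.filters.min_len,
                dust_max=config.filters.dust_max,
            )

            stage = f"align[{spec.library_id}]"
            tie_sets: dict[str, list[al.AlignmentHit]] = {}
            chosen: dict[str, al.AlignmentHit] = {}
            for read in clean:
                hits = al.exhaustive_align(
                    read,
                    panel,
                    max_edit=int(config.filters.edit_frac * len(read.sequence)),
                )
                hits = al.edit_distance_filter(hits, frac=config.filters.edit_frac)
                tie = al.best_hits(hits)
                if tie:
                    tie_sets[read.read_id] = tie
                    chosen[read.read_id] = dmg.choose_damage_hit(tie)

            stage = f"assign[{spec.library_id}]"
            assignments, alog = asg.assign_all(tie_sets, acc_map, tree)
        except Exception as exc:  # noqa: BLE001 - context for any stage failure
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc

        per_library_assignments[spec.library_id] = assignments
        reads_by_library[spec.library_id] = {r.read_id: r for r in clean}
        chosen_hits_by_library[spec.library_id] = chosen
        metas.append(
            prof.LibraryMeta(
                library_id=spec.library_id,
                site=spec.site,
                layer=spec.layer,
                culture=spec.culture,
                library_type=spec.library_type,
                n_reads_analysed=report.n_after_dust,
            )
        )
        manifest["libraries"][spec.library_id] = {
            "n_simulated": len(reads),
            "filters": dataclasses.asdict(report),
            "n_with_hits": len(tie_sets),
            "n_assigned": alog.n_assigned,
            "n_unassigned": alog.n_unassigned,
            "n_dropped_unmapped": alog.n_dropped_unmapped,
        }
        if write:
            (out / f"{spec.library_id}.assignments.tsv").write_text(
                asg.assignments_to_tsv(assignments, tree)
            )

    # --- per-layer profiles ------------------------------------------------
    layer_profiles = prof.merge_layers(per_library_assignments, metas)
    collapsed = {
        key: prof.collapse_taxa(p, tree) for key, p in layer_profiles.items()
    }
    frame = prof.profiles_to_frame(collapsed, tree)
    manifest["profiles"] = {
        f"{site}/{layer}": {
            "total_assigned": p.total_assigned(),
            "total_reads_analysed": p.total_reads_analysed,
            "vertebrate_concentration": prof.vertebrate_concentration(p, tree)
            if p.total_reads_analysed
            else None,
        }
        for (site, layer), p in collapsed.items()
    }
    if write and not frame.empty:
        frame.to_csv(out / "layer_profiles.tsv", sep="\t", index=False)

    # --- damage ------------------------------------------------------------
    manifest["damage"] = {}
    for spec in config.libraries:
        by_taxid: dict[int, list[al.AlignmentHit]] = {}
        assigned_taxid = {
            a.read_id: a.taxid for a in per_library_assignments[spec.library_id]
        }
        for read_id, hit in chosen_hits_by_library[spec.library_id].items():
            taxid = assigned_taxid.get(read_id)
            if taxid is not None:
                by_taxid.setdefault(taxid, []).append(hit)
        for taxid, hits in sorted(by_taxid.items()):
            est = dmg.ct_frequency(
                hits,
                reads_by_library[spec.library_id],
                panel,
                taxon=tree.name(taxid),
                min_reads=config.filters.damage_min_reads,
            )
            if est is not None:
                manifest["damage"][f"{spec.library_id}:{tree.name(taxid)}"] = {
                    "n_reads": est.n_reads_used,
                    "freq_ct_pos1": est.freq_ct_pos1,
                }

    # --- ordination --------------------------------------------------------
    keys = sorted(collapsed)
    if len(keys) >= 3:
        taxa = sorted({t for p in collapsed.values() for t in p.counts})
        vectors = [
            [collapsed[k].counts.get(t, 0) for t in taxa] for k in keys
        ]
        diss = st.dissimilarity_matrix(vectors)
        ordn = st.nmds(
            diss,
            seed=config.seed,
            restarts=config.nmds_restarts,
            labels=["/".join(k) for k in keys],
        )
        manifest["ordination"] = {
            "stress": ordn.stress,
            "labels": list(ordn.labels),
        }
        if write:
            lines = ["layer\taxis1\taxis2"]
            for lab, xy in zip(ordn.labels, ordn.coords):
                lines.append(f"{lab}\t{xy[0]:.6f}\t{xy[1]:.6f}")
            (out / "nmds_coordinates.tsv").write_text("\n".join(lines) + "\n")

    # --- biomass correlation ----------------------------------------------
    if config.biomass:
        total_counts: dict[str, int] = {}
        for p in collapsed.values():
            for taxid, n in p.counts.items():
                total_counts[tree.name(taxid)] = (
                    total_counts.get(tree.name(taxid), 0) + n
                )
        try:
            corr = st.correlate_profiles(total_counts, config.biomass)
            manifest["biomass_correlation"] = {
                "rho": corr.rho,
                "p_two_sided": corr.p_two_sided,
                "n": corr.n,
            }
        except ValueError as exc:
            manifest["biomass_correlation"] = {"error": str(exc)}

    # --- consensus ---------------------------------------------------------
    if config.consensus_taxon:
        taxid = tree.find_name(config.consensus_taxon)
        acc = next(a for a, t in acc_map.items() if t == taxid)
        all_hits, all_reads = [], {}
        for spec in config.libraries:
            assigned_taxid = {
                a.read_id: a.taxid
                for a in per_library_assignments[spec.library_id]
            }
            for read_id, hit in chosen_hits_by_library[spec.library_id].items():
                if (
                    assigned_taxid.get(read_id) == taxid
                    and hit.ref_accession == acc
                ):
                    all_hits.append(hit)
                    all_reads[read_id] = reads_by_library[spec.library_id][read_id]
        cons = pileup_consensus(all_hits, all_reads, acc, panel[acc])
        manifest["consensus"] = {
            "taxon": config.consensus_taxon,
            "n_reads": cons.n_reads,
            "mean_depth": cons.mean_depth,
        }
        if write:
            (out / "consensus.fasta").write_text(
                f">{acc}_consensus depth={cons.mean_depth:.2f}\n{cons.sequence}\n"
            )

    if write:
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return manifest
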