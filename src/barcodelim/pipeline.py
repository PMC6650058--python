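"""End-to-end orchestration: distances -> trees -> assignment -> ABGD -> GMYC.

The pipeline is a pure function of (inputs, options, seed). Native trees are
NJ with bootstrap; externally built trees (ML/BI/chronograms in Newick) can
be supplied per locus and enter the per-gene majority vote alongside the
native NJ tree, reproducing a multi-inference design. Outputs are plain TSV
tables plus a JSON manifest recording the seed and stage statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abgd import AbgdConfig, AbgdResult, Partition, abgd_sweep, select_partition, sweep_table
from .assignment import (
    DISCORDANT,
    FinalCall,
    SynonymMap,
    assign_on_tree,
    build_synonym_map,
    combine_genes,
    composition_report,
    delimitation_comparison,
    gene_majority,
)
from .distances import DistanceMatrix, distance_matrix
from .gmyc import GmycFit, collapse_haplotypes, gmyc_fit, ultrametricize
from .seqio import (
    Alignment,
    read_fasta,
    read_metadata,
    read_newick,
    read_reference_table,
)
from .trees import TreeInferenceConfig, bootstrap_supports, root_with_outgroup

OUTGROUP_LABEL_DEFAULT = "Outgroup_sp"


@dataclass
class PipelineOptions:
    """Tunable behaviour of one pipeline run."""

    n_bootstrap: int = 1000
    seed: int = 0
    deletion_mode: str = "complete"
    tree_method: str = "nj"
    abgd: AbgdConfig = field(default_factory=AbgdConfig)
    synonym_threshold: float = 0.002
    support_threshold: float = 70.0
    gmyc_boundary_correction: bool = False
    aliases: dict[str, str] = field(default_factory=dict)
    outgroup_species_label: str = OUTGROUP_LABEL_DEFAULT


@dataclass
class LocusResult:
    locus: str
    dm: DistanceMatrix
    trees: list[dendropy.Tree]
    tree_sources: list[str]
    calls_per_tree: dict[str, list[str | None]]
    majority: dict[str, str | None]
    abgd_results: list[AbgdResult]
    abgd_selected: AbgdResult
    gmyc: GmycFit | None
    gmyc_entities: Partition | None
    n_haplotypes: int


@dataclass
class PipelineResult:
    options: PipelineOptions
    loci: list[LocusResult]
    synonyms: SynonymMap
    final_calls: dict[str, FinalCall]
    assignment_table: pd.DataFrame
    composition: pd.DataFrame
    comparison: pd.DataFrame
    diagnostics: dict
    manifest: dict


def validate_inputs(
    alignments: list[Alignment],
    metadata: pd.DataFrame,
    references: pd.DataFrame,
) -> dict:
    """Cross-check id spaces; non-fatal warnings for single-locus specimens.

    Fatal only when no specimen occurs in any alignment, or a reference id is
    absent from its locus' alignment.
    """
    diagnostics: dict = {"warnings": [], "errors": []}
    meta_ids = set(metadata["specimen_id"])
    specimen_sets = []
    for aln in alignments:
        specs = set(aln.ids_with_role("specimen"))
        specimen_sets.append(specs)
        refs_locus = references[references["locus"].isin([aln.locus_name, ""])]
        missing = [
            r for r in refs_locus["sequence_id"]
            if r not in set(aln.ids)
        ]
        if missing:
            diagnostics["errors"].append(
                f"reference ids absent from {aln.locus_name} alignment: {missing[:10]}"
            )
    all_specs = set().union(*specimen_sets) if specimen_sets else set()
    if not all_specs & meta_ids:
        diagnostics["errors"].append(
            "no overlap between metadata specimen ids and alignment specimens"
        )
    orphans = sorted(all_specs - meta_ids)
    if orphans:
        diagnostics["warnings"].append(
            f"specimens missing from metadata: {orphans[:10]}"
        )
    for aln, specs in zip(alignments, specimen_sets):
        dropped = sorted(all_specs - specs)
        if dropped:
            diagnostics["warnings"].append(
                f"{len(dropped)} specimens missing from {aln.locus_name}: {dropped[:10]}"
            )
    if diagnostics["errors"]:
        raise ValueError("; ".join(diagnostics["errors"]))
    return diagnostics


def _prefilter_saturated(dm: DistanceMatrix, diagnostics: dict) -> DistanceMatrix:
    """Drop ids greedily until no undefined (saturated) pairs remain."""
    keep = list(dm.ids)
    sub = dm
    while True:
        undef = sub.undefined_pairs()
        if not undef:
            return sub
        counts: dict[str, int] = {}
        for a, b in undef:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        worst = max(sorted(counts), key=lambda s: counts[s])
        keep.remove(worst)
        diagnostics.setdefault("saturated_dropped", []).append(worst)
        sub = dm.submatrix(keep)


def _augment_outgroup_refs(
    references: pd.DataFrame, aln: Alignment, label: str
) -> pd.DataFrame:
    """Add outgroup tips as a pseudo-species so conflicts become discordance."""
    known = set(references["sequence_id"])
    rows = [
        {"sequence_id": og, "species": label, "locus": aln.locus_name, "accession": ""}
        for og in aln.ids_with_role("outgroup")
        if og not in known
    ]
    if rows:
        return pd.concat([references, pd.DataFrame(rows)], ignore_index=True)
    return references


def run_pipeline(
    alignments: list[Alignment],
    metadata: pd.DataFrame,
    references: pd.DataFrame,
    external_trees: dict[str, list[dendropy.Tree]] | None = None,
    options: PipelineOptions | None = None,
    output_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full two-gene species-delimitation workflow.

    ``references`` must carry columns sequence_id, species, locus (empty
    locus = applies to every locus). ``external_trees`` maps locus name to
    additional rooted or rootable Newick trees that join the majority vote.
    """
    opts = options or PipelineOptions()
    external_trees = external_trees or {}
    diagnostics = validate_inputs(alignments, metadata, references)

    loci: list[LocusResult] = []
    synonym_merges: dict[str, str] = {}
    for locus_idx, aln in enumerate(alignments):
        refs_locus = _augment_outgroup_refs(
            references[references["locus"].isin([aln.locus_name, ""])].copy(),
            aln,
            opts.outgroup_species_label,
        )
        dm = distance_matrix(aln, opts.deletion_mode)
        outgroup_ids = aln.ids_with_role("outgroup")

        native = bootstrap_supports(
            aln,
            TreeInferenceConfig(
                method=opts.tree_method,
                n_bootstrap=opts.n_bootstrap,
                seed=opts.seed + locus_idx,
                deletion_mode=opts.deletion_mode,
            ),
            outgroup_ids=outgroup_ids or None,
            allow_superset_root=True,
        )
        trees = [native]
        sources = ["native_" + opts.tree_method]
        for k, ext in enumerate(external_trees.get(aln.locus_name, [])):
            if not ext.is_rooted and outgroup_ids:
                ext = root_with_outgroup(
                    ext, outgroup_ids, fallback_midpoint=True, allow_superset=True
                )
            trees.append(ext)
            sources.append(f"external_{k + 1}")

        specimens = aln.ids_with_role("specimen")
        calls_per_tree: dict[str, list[str | None]] = {s: [] for s in specimens}
        for tree in trees:
            calls = assign_on_tree(tree, refs_locus, dm, specimens)
            for s in specimens:
                calls_per_tree[s].append(calls[s])
        majority = {s: gene_majority(calls_per_tree[s]) for s in specimens}

        syn = build_synonym_map(
            refs_locus, dm, threshold=opts.synonym_threshold, aliases=opts.aliases
        )
        synonym_merges.update(syn.canonical)

        dm_clean = _prefilter_saturated(dm, diagnostics)
        abgd_results = abgd_sweep(dm_clean, opts.abgd)
        abgd_selected = select_partition(abgd_results)

        # GMYC runs on the ingroup only (outgroup tips are excluded from the
        # chronogram, as is standard when the tree prior assumes one clock)
        gmyc_res: GmycFit | None = None
        gmyc_entities: Partition | None = None
        ingroup = [i for i in aln.ids if aln.roles[i] != "outgroup"]
        collapsed, hap_map = collapse_haplotypes(aln.subset(ingroup))
        try:
            chronogram = ultrametricize(alignment=collapsed)
            gmyc_res = gmyc_fit(
                chronogram,
                seed=opts.seed + locus_idx,
                boundary_correction=opts.gmyc_boundary_correction,
            )
            gmyc_entities = hap_map.expand(gmyc_res.entities)
        except ValueError as exc:
            diagnostics["warnings"].append(
                f"GMYC skipped for {aln.locus_name}: {exc}"
            )
        loci.append(
            LocusResult(
                locus=aln.locus_name,
                dm=dm,
                trees=trees,
                tree_sources=sources,
                calls_per_tree=calls_per_tree,
                majority=majority,
                abgd_results=abgd_results,
                abgd_selected=abgd_selected,
                gmyc=gmyc_res,
                gmyc_entities=gmyc_entities,
                n_haplotypes=hap_map.n_haplotypes,
            )
        )

    synonyms = SynonymMap(dict(synonym_merges))
    all_specimens = sorted(
        {s for locus in loci for s in locus.majority}
    )
    final_calls: dict[str, FinalCall] = {}
    for sid in all_specimens:
        per_gene = [
            locus.majority.get(sid) for locus in loci
        ]
        g1 = per_gene[0] if len(per_gene) > 0 else None
        g2 = per_gene[1] if len(per_gene) > 1 else None
        final_calls[sid] = combine_genes(g1, g2, synonyms)

    assignment_rows = []
    for sid in all_specimens:
        row: dict = {"specimen_id": sid}
        for locus in loci:
            for src, call in zip(
                locus.tree_sources, locus.calls_per_tree.get(sid, [])
            ):
                row[f"{locus.locus}.{src}"] = call or ""
            row[f"{locus.locus}.majority"] = locus.majority.get(sid) or ""
        fc = final_calls[sid]
        row["final"] = fc.status
        row["single_gene"] = fc.single_gene
        assignment_rows.append(row)
    assignment_table = pd.DataFrame(assignment_rows)

    meta_subset = metadata[metadata["specimen_id"].isin(all_specimens)]
    composition = composition_report(final_calls, meta_subset)

    partitions: dict[str, Partition] = {}
    for locus in loci:
        partitions[f"abgd_{locus.locus}"] = locus.abgd_selected.initial
        if locus.gmyc_entities is not None:
            partitions[f"gmyc_{locus.locus}"] = locus.gmyc_entities
    comparison = delimitation_comparison(final_calls, partitions)

    manifest = {
        "package_version": __version__,
        "seed": opts.seed,
        "n_bootstrap": opts.n_bootstrap,
        "deletion_mode": opts.deletion_mode,
        "synonym_threshold": opts.synonym_threshold,
        "loci": [
            {
                "locus": locus.locus,
                "n_sequences": locus.dm.n,
                "n_haplotypes": locus.n_haplotypes,
                "tree_sources": locus.tree_sources,
                "abgd_selected_prior": locus.abgd_selected.prior,
                "abgd_selected_gap_width": locus.abgd_selected.gap_width,
                "abgd_n_ip": locus.abgd_selected.initial.n_groups,
                "abgd_n_rp": locus.abgd_selected.recursive.n_groups,
                "gmyc": locus.gmyc.to_dict() if locus.gmyc else None,
            }
            for locus in loci
        ],
        "n_specimens": len(all_specimens),
        "n_discordant": sum(
            1 for c in final_calls.values() if c.status == DISCORDANT
        ),
        "synonym_groups": synonyms.groups(),
        "diagnostics": diagnostics,
    }
    result = PipelineResult(
        options=opts,
        loci=loci,
        synonyms=synonyms,
        final_calls=final_calls,
        assignment_table=assignment_table,
        composition=composition,
        comparison=comparison,
        diagnostics=diagnostics,
        manifest=manifest,
    )
    if output_dir is not None:
        write_report_bundle(result, output_dir)
    return result


def write_report_bundle(result: PipelineResult, output_dir: str | Path) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.assignment_table.to_csv(out / "assignment.tsv", sep="\t", index=False)
    result.composition.to_csv(out / "composition.tsv", sep="\t", index=False)
    result.comparison.to_csv(out / "comparison.tsv", sep="\t", index=False)
    for locus in result.loci:
        sweep_table(locus.abgd_results).to_csv(
            out / f"abgd_sweep_{locus.locus}.tsv", sep="\t", index=False
        )
        if locus.gmyc is not None:
            (out / f"gmyc_{locus.locus}.json").write_text(
                json.dumps(locus.gmyc.to_dict(), indent=1)
            )
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))


# -- file-based entry point ------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_from_config(path: str | Path, output_dir: str | Path) -> PipelineResult:
    """Run the pipeline from a declarative YAML config.

    Expected keys: ``loci`` (list of {name, fasta, external_trees: [paths]}),
    ``metadata``, ``references``, ``outgroup_ids`` (optional), and any
    :class:`PipelineOptions` field under ``options``.
    """
    cfg = load_config(path)
    base = Path(path).parent
    alignments = []
    external: dict[str, list[dendropy.Tree]] = {}
    outgroup_ids = set(cfg.get("outgroup_ids", []))
    ref_df = read_reference_table(base / cfg["references"])
    for locus_cfg in cfg["loci"]:
        role_map = {og: "outgroup" for og in outgroup_ids}
        for rid in ref_df["sequence_id"]:
            role_map.setdefault(rid, "reference")
        aln = read_fasta(
            base / locus_cfg["fasta"], locus_name=locus_cfg["name"], role_map=role_map
        )
        alignments.append(aln)
        for tree_path in locus_cfg.get("external_trees", []):
            external.setdefault(locus_cfg["name"], []).append(
                read_newick(base / tree_path)
            )
    metadata = read_metadata(base / cfg["metadata"])
    opt_kwargs = cfg.get("options", {})
    abgd_kwargs = opt_kwargs.pop("abgd", None)
    options = PipelineOptions(**opt_kwargs)
    if abgd_kwargs:
        options.abgd = AbgdConfig(
            priors=tuple(abgd_kwargs.get("priors", AbgdConfig().priors)),
            gap_widths=tuple(abgd_kwargs.get("gap_widths", AbgdConfig().gap_widths)),
        )
    return run_pipeline(
        alignments, metadata, ref_df,
        external_trees=external or None,
        options=options,
        output_dir=output_dir,
    )
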