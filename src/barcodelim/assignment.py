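"""Tree-based specimen-to-species assignment and the consensus decision rules.

The decision procedure mirrors a standard multi-marker barcoding workflow:

1. curate a reference library (keep up to two representatives per species
   whose conspecifics form a supported monophyletic clade; discard sequences
   clustering with distantly related species);
2. on each rooted gene tree, assign every specimen the species of the
   smallest clade containing it and at least one reference (breaking
   multi-species clades by lowest mean K2P to the specimen);
3. per gene, take the strict-majority call across tree inferences;
4. across genes, accept agreement (after synonym mapping), label
   disagreement "discordant", fall back to the single available gene, and
   call "unidentified" when neither gene assigns;
5. collapse reference species with near-zero between-species divergence into
   synonyms.

References to the outgroup are treated as a pseudo-species so that
specimen-vs-outgroup conflicts fall under the same discordance rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .abgd import Partition
from .distances import DistanceMatrix, distance_matrix
from .seqio import Alignment
from .trees import (
    TreeInferenceConfig,
    _leafsets,
    bootstrap_supports,
    get_support,
)

UNASSIGNED = None
DISCORDANT = "discordant"
UNIDENTIFIED = "unidentified"


@dataclass
class SynonymMap:
    """species name -> canonical name; idempotent (canonical maps to itself)."""

    canonical: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # resolve chains, then assert idempotence
        resolved = {}
        for name in self.canonical:
            target = name
            seen = set()
            while target in self.canonical and self.canonical[target] != target:
                if target in seen:
                    raise ValueError(f"synonym cycle involving {name!r}")
                seen.add(target)
                target = self.canonical[target]
            resolved[name] = target
        for t in set(resolved.values()):
            resolved[t] = t
        self.canonical = resolved

    def apply(self, name: str | None) -> str | None:
        if name is None:
            return None
        return self.canonical.get(name, name)

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for name, canon in sorted(self.canonical.items()):
            out.setdefault(canon, []).append(name)
        return out


@dataclass
class FinalCall:
    """Combined two-gene call for one specimen."""

    status: str                      # species name | "discordant" | "unidentified"
    gene_calls: tuple[str | None, str | None]
    single_gene: bool = False

    @property
    def is_species(self) -> bool:
        return self.status not in (DISCORDANT, UNIDENTIFIED)


# -- reference curation ----------------------------------------------------

@dataclass
class CurationConfig:
    support_threshold: float = 70.0
    max_per_species: int = 2
    n_bootstrap: int = 200
    seed: int = 0


def curate_references(
    alignment: Alignment,
    labels: Mapping[str, str],
    config: CurationConfig | None = None,
    tree: dendropy.Tree | None = None,
    dm: DistanceMatrix | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Select up to two reference representatives per candidate species.

    ``labels`` maps candidate sequence ids to claimed species names; ids with
    role ``outgroup`` in the alignment root the curation tree. A species'
    candidates must form a monophyletic clade with bootstrap support at or
    above the threshold (clades without a recorded support pass on topology
    alone); single candidates are trivially monophyletic. When monophyly
    fails, candidates whose removal restores it *and* whose nearest K2P
    neighbour is heterospecific are discarded as misplaced. The kept pair is
    the two most mutually divergent conspecifics.

    Returns the reference table and a report of discarded/rejected ids.
    """
    cfg = config or CurationConfig()
    outgroup_ids = alignment.ids_with_role("outgroup")
    if not outgroup_ids:
        raise ValueError("curation requires outgroup sequences for rooting")
    if dm is None:
        dm = distance_matrix(alignment, deletion_mode="complete")
    if tree is None:
        tree = bootstrap_supports(
            alignment,
            TreeInferenceConfig(
                method="nj", n_bootstrap=cfg.n_bootstrap, seed=cfg.seed
            ),
            outgroup_ids=outgroup_ids,
        )
    clades = {frozenset(v): k for k, v in _leafsets(tree).items()}

    def clade_support(members: frozenset) -> float | None:
        node = clades.get(members)
        if node is None:
            return None  # not a clade at all
        s = get_support(node)
        return s if s is not None else float("inf")  # no support recorded: pass

    def nearest_is_heterospecific(cand: str) -> bool:
        i = dm.index(cand)
        row = np.where(dm.defined[i], dm.d[i], np.inf).copy()
        row[i] = np.inf
        for og in outgroup_ids:
            row[dm.index(og)] = np.inf
        j = int(np.argmin(row))
        return labels.get(dm.ids[j]) != labels[cand]

    species_names = sorted(set(labels.values()))
    kept_rows = []
    report: dict[str, list[str]] = {"discarded": [], "rejected_species": []}
    for sp in species_names:
        cands = [i for i in alignment.ids if labels.get(i) == sp]
        pool = list(cands)
        while len(pool) > 1:
            s = clade_support(frozenset(pool))
            if s is not None and s >= cfg.support_threshold:
                break
            # try to restore monophyly by removing one misplaced candidate
            removed = None
            for c in pool:
                rest = [x for x in pool if x != c]
                if len(rest) == 1 or clade_support(frozenset(rest)) is not None:
                    if nearest_is_heterospecific(c):
                        removed = c
                        break
            if removed is None:
                pool = []
                break
            report["discarded"].append(removed)
            pool.remove(removed)
        if not pool:
            report["rejected_species"].append(sp)
            continue
        keep = _most_divergent_pair(pool, dm, cfg.max_per_species)
        for sid in keep:
            kept_rows.append(
                {"sequence_id": sid, "species": sp,
                 "locus": alignment.locus_name, "accession": ""}
            )
    refs = pd.DataFrame(kept_rows, columns=["sequence_id", "species", "locus", "accession"])
    return refs, report


def _most_divergent_pair(pool: Sequence[str], dm: DistanceMatrix, k: int) -> list[str]:
    if len(pool) <= k:
        return sorted(pool)
    best, best_d = None, -1.0
    for a_idx in range(len(pool)):
        for b_idx in range(a_idx + 1, len(pool)):
            a, b = pool[a_idx], pool[b_idx]
            d = dm.get(a, b)
            if d > best_d:
                best_d, best = d, (a, b)
    return sorted(best)


# -- per-tree assignment ---------------------------------------------------

def assign_on_tree(
    tree: dendropy.Tree,
    references: pd.DataFrame,
    dm: DistanceMatrix,
    specimen_ids: Iterable[str] | None = None,
) -> dict[str, str | None]:
    """Assign each specimen the species of its smallest reference-containing clade.

    The tree must be rooted. For each specimen tip, walk rootward to the first
    ancestor whose clade contains >= 1 reference; a single reference species
    gives the call, several are resolved by lowest mean K2P between the
    specimen and each species' references in that clade. If the first such
    ancestor is the root, the specimen is unassigned (None).
    """
    if not tree.is_rooted:
        raise ValueError("assign_on_tree requires a rooted tree")
    species_of_ref = dict(zip(references["sequence_id"], references["species"]))
    tip_nodes = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing_refs = [r for r in species_of_ref if r not in tip_nodes]
    leafsets = _leafsets(tree)
    if specimen_ids is None:
        specimen_ids = [t for t in tip_nodes if t not in species_of_ref]
    calls: dict[str, str | None] = {}
    for sid in specimen_ids:
        node = tip_nodes.get(sid)
        if node is None:
            raise ValueError(f"specimen {sid!r} not a tip of the tree")
        anc = node.parent_node
        while anc is not None:
            refs_here = [r for r in leafsets[anc] if r in species_of_ref]
            if refs_here:
                break
            anc = anc.parent_node
        if anc is None or anc.parent_node is None:
            calls[sid] = UNASSIGNED  # first reference-containing clade is the root
            continue
        species_here = sorted({species_of_ref[r] for r in refs_here})
        if len(species_here) == 1:
            calls[sid] = species_here[0]
            continue
        i = dm.index(sid)
        best_sp, best_d = None, np.inf
        for sp in species_here:
            ref_ids = [r for r in refs_here if species_of_ref[r] == sp]
            ds = [
                dm.d[i, dm.index(r)]
                for r in ref_ids
                if dm.defined[i, dm.index(r)]
            ]
            if ds and np.mean(ds) < best_d:
                best_d, best_sp = float(np.mean(ds)), sp
        calls[sid] = best_sp
    return calls


def gene_majority(calls: Sequence[str | None]) -> str | None:
    """Strict-majority species call across tree inferences for one gene.

    A species must win more than half of all tree calls (unassigned calls
    count toward the denominator); otherwise unassigned.
    """
    if not calls:
        return UNASSIGNED
    counts: dict[str, int] = {}
    for c in calls:
        if c is not None:
            counts[c] = counts.get(c, 0) + 1
    if not counts:
        return UNASSIGNED
    best = max(sorted(counts), key=lambda s: counts[s])
    if counts[best] * 2 > len(calls):
        return best
    return UNASSIGNED


def combine_genes(
    call_gene1: str | None,
    call_gene2: str | None,
    synonyms: SynonymMap | None = None,
) -> FinalCall:
    """Combine per-gene majority calls into the final species decision."""
    syn = synonyms or SynonymMap()
    c1, c2 = syn.apply(call_gene1), syn.apply(call_gene2)
    raw = (call_gene1, call_gene2)
    if c1 is not None and c2 is not None:
        if c1 == c2:
            return FinalCall(status=c1, gene_calls=raw)
        return FinalCall(status=DISCORDANT, gene_calls=raw)
    if c1 is not None:
        return FinalCall(status=c1, gene_calls=raw, single_gene=True)
    if c2 is not None:
        return FinalCall(status=c2, gene_calls=raw, single_gene=True)
    return FinalCall(status=UNIDENTIFIED, gene_calls=raw)


def build_synonym_map(
    references: pd.DataFrame,
    dm: DistanceMatrix,
    threshold: float = 0.002,
    aliases: Mapping[str, str] | None = None,
) -> SynonymMap:
    """Merge reference species whose between-species mean K2P is below threshold.

    Merging is transitive (single linkage over species). The canonical name
    is the alphabetically first member unless the alias table names another.
    """
    species = sorted(set(references["species"]))
    members = {
        sp: [r for r, s in zip(references["sequence_id"], references["species"]) if s == sp]
        for sp in species
    }
    parent = {sp: sp for sp in species}

    def find(s: str) -> str:
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            a, b = species[i], species[j]
            vals = []
            for ra in members[a]:
                for rb in members[b]:
                    ia, ib = dm.index(ra), dm.index(rb)
                    if dm.defined[ia, ib]:
                        vals.append(dm.d[ia, ib])
            if vals and float(np.mean(vals)) < threshold:
                ra_, rb_ = find(a), find(b)
                if ra_ != rb_:
                    parent[max(ra_, rb_)] = min(ra_, rb_)

    canonical = {}
    groups: dict[str, list[str]] = {}
    for sp in species:
        groups.setdefault(find(sp), []).append(sp)
    alias = dict(aliases or {})
    for root_name, group in groups.items():
        if len(group) == 1 and group[0] not in alias:
            continue
        canon = min(group)
        for g in group:
            if g in alias:
                canon = alias[g]
                break
        for g in group:
            canonical[g] = canon
    for g, target in alias.items():
        canonical.setdefault(g, target)
    return SynonymMap(canonical)


# -- reports ---------------------------------------------------------------

def composition_report(
    final_calls: Mapping[str, FinalCall],
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Per-species composition: counts, relative frequency (%), sites.

    One row per assigned species plus rows for discordant/unidentified
    specimens and a totals row. Percentages are rendered to one decimal.
    """
    site_of = dict(zip(metadata["specimen_id"], metadata["site_code"]))
    missing_sites = [s for s in final_calls if site_of.get(s, "") == ""]
    if missing_sites:
        raise ValueError(
            f"specimens without a site code in the metadata: {missing_sites[:10]}"
        )
    total = len(final_calls)
    by_cat: dict[str, list[str]] = {}
    for sid, call in final_calls.items():
        by_cat.setdefault(call.status, []).append(sid)

    rows = []
    species_cats = sorted(
        (c for c in by_cat if c not in (DISCORDANT, UNIDENTIFIED)),
        key=lambda c: (-len(by_cat[c]), c),
    )
    order = species_cats + [c for c in (DISCORDANT, UNIDENTIFIED) if c in by_cat]
    for cat in order:
        sids = by_cat[cat]
        sites = sorted({site_of[s] for s in sids})
        rows.append(
            {
                "category": cat,
                "n_specimens": len(sids),
                "rel_freq_pct": round(100.0 * len(sids) / total, 1),
                "n_sites": len(sites),
                "sites": ",".join(sites),
            }
        )
    rows.append(
        {
            "category": "total",
            "n_specimens": total,
            "rel_freq_pct": 100.0,
            "n_sites": len({site_of[s] for s in final_calls}),
            "sites": "",
        }
    )
    return pd.DataFrame(rows)


def delimitation_comparison(
    final_calls: Mapping[str, FinalCall],
    partitions: Mapping[str, Partition],
) -> pd.DataFrame:
    """Per-species count of delimitation groups intersecting its specimens.

    ``partitions`` maps a method label (e.g. "abgd_tufA", "gmyc_ITS") to a
    partition over sequence ids. Reference-only groups (containing none of
    the assigned specimens) are reported on their own row, and a totals row
    gives each partition's full group count.
    """
    species = sorted({c.status for c in final_calls.values() if c.is_species})
    rows = []
    for sp in species:
        sids = [s for s, c in final_calls.items() if c.status == sp]
        row: dict = {"species": sp, "n_specimens": len(sids)}
        for method, part in partitions.items():
            groups = {part.group_of[s] for s in sids if s in part.group_of}
            row[method] = len(groups)
        rows.append(row)
    specimen_ids = set(final_calls)
    row = {"species": "reference-only groups", "n_specimens": 0}
    for method, part in partitions.items():
        ref_groups = {
            g for s, g in part.group_of.items() if s not in specimen_ids
        }
        spec_groups = {
            g for s, g in part.group_of.items() if s in specimen_ids
        }
        row[method] = len(ref_groups - spec_groups)
    rows.append(row)
    row = {"species": "total groups", "n_specimens": len(final_calls)}
    for method, part in partitions.items():
        row[method] = part.n_groups
    rows.append(row)
    return pd.DataFrame(rows)
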