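"""Two-locus synthetic specimen datasets with known ground truth.

The generator emulates the statistical structure a multi-marker barcoding
survey assumes: a Yule species tree whose depth is calibrated so the mean
between-species sequence divergence hits a target delta_inter; independent
single-population Kingman coalescents within each species calibrated to a
target within-species divergence delta_intra; K80(kappa) sequence evolution
with per-locus rate multipliers; an outgroup clade; optional gene-discordant
specimens (species membership swapped at one locus only, the phenotype a
specimen with introgressed or misidentified material shows in real data);
and optional synonym reference pairs (a second species label whose reference
sequences are identical copies, i.e. ~0 divergence).

Branch lengths are in expected substitutions per site, so a path length is
directly the expected K2P divergence of the pair (K2P is consistent under
K80). Calibration rescales the realized trees, making
:func:`expected_divergence` an exact closed form rather than an approximation.

No indels are simulated; gap handling is exercised by hand-built fixtures.
Identical config + seed gives bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .seqio import Alignment

OUTGROUP_SPECIES = "Outgroup_sp"


@dataclass
class SimulationConfig:
    """Study-design knobs; defaults mirror a 215-specimen, 9-species survey."""

    n_species: int = 9
    specimens_per_species: tuple[int, ...] = (74, 47, 30, 13, 9, 8, 4, 4, 4)
    references_per_species: int = 2
    outgroup_tips: int = 3
    outgroup_specimens: int = 14
    delta_intra: float = 0.004
    delta_inter: float = 0.06
    kappa: float = 2.0
    locus_names: tuple[str, ...] = ("tufA", "ITS")
    locus_rate_multipliers: tuple[float, ...] = (1.0, 1.3)
    locus_lengths: tuple[int, ...] = (813, 732)
    n_discordant: int = 8
    n_synonym_pairs: int = 2
    n_sites: int = 23
    outgroup_depth_multiplier: float = 2.0
    depth_multiplier: float = 1.0       # scales the species (Yule) tree depth
    intra_depth_multiplier: float = 1.0 # scales the coalescent (tuft) depth
    mutation_scale: float = 1.0         # 0 => no substitutions at all
    min_inter_fraction: float = 0.5     # closest species pair >= this x delta_inter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("need n_species >= 1")
        if len(self.specimens_per_species) != self.n_species:
            raise ValueError("specimens_per_species length must equal n_species")
        if not self.delta_intra < self.delta_inter:
            raise ValueError("delta_intra must be < delta_inter")
        for L in self.locus_lengths:
            if L < 100:
                raise ValueError("locus lengths must be >= 100")
        if not (
            len(self.locus_names)
            == len(self.locus_rate_multipliers)
            == len(self.locus_lengths)
        ):
            raise ValueError("locus settings must have equal lengths")
        if self.n_synonym_pairs > self.n_species:
            raise ValueError("more synonym pairs than species")
        if self.n_discordant > 0 and self.n_species < 2:
            raise ValueError("discordant specimens need >= 2 species")


@dataclass
class GroundTruth:
    """What the generator knows: true species, discordants, synonyms, trees."""

    species_by_locus: list[dict[str, str]]
    final_truth: dict[str, str]          # specimen -> species or "discordant"
    discordant_ids: list[str]
    synonym_groups: list[tuple[str, str]]  # (canonical species, synonym label)
    species_tree_newick: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "species_by_locus": self.species_by_locus,
                "final_truth": self.final_truth,
                "discordant_ids": self.discordant_ids,
                "synonym_groups": [list(g) for g in self.synonym_groups],
                "species_tree_newick": self.species_tree_newick,
            },
            indent=1,
            sort_keys=True,
        )


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    alignments: list[Alignment]
    metadata: pd.DataFrame
    references: pd.DataFrame
    truth: GroundTruth


# -- minimal tree scaffolding (times in substitutions/site) ----------------

class _Node:
    __slots__ = ("children", "blen", "label")

    def __init__(self, label: str | None = None):
        self.children: list[_Node] = []
        self.blen: float = 0.0
        self.label = label

    def leaves(self) -> list["_Node"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def scale(self, f: float) -> None:
        self.blen *= f
        for c in self.children:
            c.scale(f)

    def newick(self) -> str:
        if not self.children:
            return f"{self.label}:{self.blen:.8f}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.blen:.8f}"


def _tip_depths(root: _Node) -> dict[str, float]:
    out: dict[str, float] = {}

    def rec(node: _Node, depth: float) -> None:
        d = depth + node.blen
        if not node.children:
            out[node.label] = d
        for c in node.children:
            rec(c, d)

    rec(root, -root.blen)  # root's own blen does not count toward depth
    return out


def _pairwise_mean(root: _Node) -> float:
    """Mean tip-to-tip path length (via depths and MRCA depths)."""
    leaves = [l.label for l in root.leaves()]
    if len(leaves) < 2:
        return 0.0
    depths = _tip_depths(root)
    # accumulate pair MRCA depths by recursion
    total = 0.0
    count = 0

    def rec(node: _Node, depth: float) -> list[str]:
        nonlocal total, count
        d = depth + node.blen
        if not node.children:
            return [node.label]
        groups = [rec(c, d) for c in node.children]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                for a in groups[i]:
                    for b in groups[j]:
                        total += depths[a] + depths[b] - 2 * d
                        count += 1
        merged = []
        for g in groups:
            merged.extend(g)
        return merged

    rec(root, -root.blen)
    return total / count


def _node_heights_ultra(root: _Node) -> dict[int, float]:
    """Node heights of an ultrametric tree (tips at 0), keyed by id(node)."""
    depths = _tip_depths(root)
    total = max(depths.values())
    out: dict[int, float] = {}

    def rec(node: _Node, depth: float) -> None:
        d = depth + node.blen
        out[id(node)] = total - d if node.children else 0.0
        for c in node.children:
            rec(c, d)

    rec(root, -root.blen)
    return out


def _enforce_min_height(root: _Node, h_min: float) -> None:
    """Raise internal nodes below ``h_min`` so no species pair is closer than
    2*h_min; keeps the tree ultrametric (zero-length internal branches may
    appear where nodes were clipped to the floor)."""
    heights = _node_heights_ultra(root)
    new_h: dict[int, float] = {}

    def assign(node: _Node) -> None:
        for c in node.children:
            assign(c)
        if node.children:
            floor = max(
                [h_min] + [new_h[id(c)] for c in node.children if c.children]
            )
            new_h[id(node)] = max(heights[id(node)], floor)
        else:
            new_h[id(node)] = 0.0

    assign(root)

    def set_branches(node: _Node, parent_h: float | None) -> None:
        if parent_h is not None:
            node.blen = parent_h - new_h[id(node)]
        for c in node.children:
            set_branches(c, new_h[id(node)])

    set_branches(root, None)


def _yule_tree(labels: list[str], rng: np.random.Generator) -> _Node:
    """Forward Yule (pure birth, rate 1): ultrametric tree over the labels."""
    if len(labels) == 1:
        node = _Node(labels[0])
        return node
    root = _Node()
    active = [root]
    birth = {id(root): 0.0}
    t = 0.0
    while len(active) < len(labels):
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        parent = active.pop(k)
        parent.blen = t - birth[id(parent)]
        for _ in range(2):
            child = _Node()
            parent.children.append(child)
            birth[id(child)] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / len(active))
    order = rng.permutation(len(active))
    for idx, leaf_idx in enumerate(order):
        leaf = active[leaf_idx]
        leaf.label = labels[idx]
        leaf.blen = t_end - birth[id(leaf)]
    return root


def _kingman_tree(labels: list[str], rng: np.random.Generator) -> _Node:
    """Kingman coalescent (rate C(n,2)): ultrametric tree over the labels."""
    if len(labels) == 1:
        return _Node(labels[0])
    nodes = [_Node(lab) for lab in labels]
    heights = [0.0] * len(nodes)
    t = 0.0
    while len(nodes) > 1:
        n = len(nodes)
        t += rng.exponential(2.0 / (n * (n - 1)))
        i, j = sorted(rng.choice(n, size=2, replace=False))
        parent = _Node()
        for k, h in ((i, heights[i]), (j, heights[j])):
            nodes[k].blen = t - h
            parent.children.append(nodes[k])
        nodes = [nodes[k] for k in range(n) if k not in (i, j)] + [parent]
        heights = [heights[k] for k in range(n) if k not in (i, j)] + [t]
    return nodes[0]


# -- K80 sequence evolution ------------------------------------------------

_TS_PARTNER = np.array([2, 3, 0, 1])
_TV_A = np.array([1, 0, 1, 0])
_TV_B = np.array([3, 2, 3, 2])
_BASES = np.array(list("ACGT"))


def evolve_k80(
    seq: np.ndarray, t: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve a coded sequence along a branch of t substitutions/site (K80)."""
    if t <= 0:
        return seq.copy()
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e_tv = np.exp(-4.0 * beta * t)
    e_ts = np.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e_tv + 0.5 * e_ts
    p_ts = 0.25 + 0.25 * e_tv - 0.5 * e_ts
    p_tv = 0.25 - 0.25 * e_tv  # each of the two transversions
    u = rng.random(seq.size)
    out = seq.copy()
    ts_mask = (u >= p_same) & (u < p_same + p_ts)
    tva_mask = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
    tvb_mask = u >= p_same + p_ts + p_tv
    out[ts_mask] = _TS_PARTNER[seq[ts_mask]]
    out[tva_mask] = _TV_A[seq[tva_mask]]
    out[tvb_mask] = _TV_B[seq[tvb_mask]]
    return out


def _evolve_tree(
    root: _Node,
    root_seq: np.ndarray,
    rate: float,
    kappa: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Sequences at the tips of a tree, evolving from the root sequence."""
    out: dict[str, np.ndarray] = {}

    def rec(node: _Node, seq: np.ndarray) -> None:
        seq2 = evolve_k80(seq, node.blen * rate, kappa, rng)
        if not node.children:
            out[node.label] = seq2
        for c in node.children:
            rec(c, seq2)

    rec(root, root_seq)
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[seq])


# -- main entry points -----------------------------------------------------

def expected_divergence(cfg: SimulationConfig) -> list[tuple[float, float]]:
    """Closed-form (E[delta_intra], E[delta_inter]) per locus.

    Exact by construction: the generator rescales every simulated tree so the
    mean within-species and between-species path lengths equal the configured
    targets before applying per-locus rate multipliers and the global
    mutation scale; depth multipliers act linearly (pre-saturation regime).
    """
    out = []
    for mult in cfg.locus_rate_multipliers:
        intra = cfg.delta_intra * cfg.intra_depth_multiplier * mult * cfg.mutation_scale
        inter = cfg.delta_inter * cfg.depth_multiplier * mult * cfg.mutation_scale
        out.append((intra, inter))
    return out


def simulate(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate aligned two-locus data, metadata, references and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    S = cfg.n_species
    species_names = [f"Species_{k + 1:02d}" for k in range(S)]

    # --- specimen / reference ids
    n_regular = int(sum(cfg.specimens_per_species))
    total_specimens = n_regular + cfg.n_discordant + cfg.outgroup_specimens
    width = max(3, len(str(total_specimens)))
    specimen_ids = [f"U{i + 1:0{width}d}" for i in range(total_specimens)]
    regular_ids = specimen_ids[:n_regular]
    discordant_ids = specimen_ids[n_regular : n_regular + cfg.n_discordant]
    og_specimen_ids = specimen_ids[n_regular + cfg.n_discordant :]

    species_of_regular: dict[str, str] = {}
    pos = 0
    for k, count in enumerate(cfg.specimens_per_species):
        for sid in regular_ids[pos : pos + count]:
            species_of_regular[sid] = species_names[k]
        pos += count

    ref_ids = {
        sp: [f"R{k + 1:02d}_{r + 1}" for r in range(cfg.references_per_species)]
        for k, sp in enumerate(species_names)
    }
    synonym_groups = []
    syn_ref_ids: dict[str, list[str]] = {}
    for k in range(cfg.n_synonym_pairs):
        sp = species_names[k]
        syn_name = f"{sp}_syn"
        synonym_groups.append((sp, syn_name))
        syn_ref_ids[syn_name] = [
            f"R{k + 1:02d}s_{r + 1}" for r in range(cfg.references_per_species)
        ]
    og_ref_ids = [f"OG_{r + 1}" for r in range(cfg.outgroup_tips)]

    # --- discordant species choices (per locus)
    disc_species: list[tuple[str, str]] = []
    for _ in discordant_ids:
        a, b = rng.choice(S, size=2, replace=False)
        disc_species.append((species_names[int(a)], species_names[int(b)]))

    # --- species tree (shared across loci), calibrated later per locus
    sp_tree = _yule_tree(list(species_names), rng)

    # --- per-species tuft memberships (tips shared across loci; genealogies differ)
    tuft_members: dict[str, list[str]] = {}
    for k, sp in enumerate(species_names):
        members = [s for s in regular_ids if species_of_regular[s] == sp]
        members += ref_ids[sp]
        tuft_members[sp] = members
    og_members = list(og_specimen_ids) + og_ref_ids

    alignments: list[Alignment] = []
    species_by_locus: list[dict[str, str]] = []
    reference_rows = []

    for locus_idx, (locus, mult, length) in enumerate(
        zip(cfg.locus_names, cfg.locus_rate_multipliers, cfg.locus_lengths)
    ):
        rate = mult * cfg.mutation_scale
        # per-locus genealogies
        tufts = {
            sp: _kingman_tree(list(tuft_members[sp]), rng) for sp in species_names
        }
        og_tree = _kingman_tree(list(og_members), rng) if og_members else None

        # calibrate tuft depths: mean pairwise within-species path = delta_intra
        tuft_depth_mean = 0.0
        n_multi = 0
        for sp, tree in tufts.items():
            if len(tuft_members[sp]) >= 2:
                m = _pairwise_mean(tree)
                if m > 0:
                    tree.scale(cfg.delta_intra * cfg.intra_depth_multiplier / m)
                n_multi += 1
        if og_tree is not None and len(og_members) >= 2:
            m = _pairwise_mean(og_tree)
            if m > 0:
                og_tree.scale(cfg.delta_intra * cfg.intra_depth_multiplier / m)
        tip_depth = {
            sp: float(np.mean(list(_tip_depths(t).values()))) for sp, t in tufts.items()
        }
        mean_tuft_tip_depth = float(np.mean(list(tip_depth.values())))

        # calibrate species tree: mean between-species specimen path = delta_inter
        sp_tree_locus = _clone(sp_tree)
        if S >= 2:
            target = cfg.delta_inter * cfg.depth_multiplier - 2 * mean_tuft_tip_depth
            if target <= 0:
                raise ValueError(
                    "delta_inter too small relative to within-species depth; "
                    "increase delta_inter or lower delta_intra"
                )
            # calibrate the mean, then guarantee the closest species pair is
            # no nearer than min_inter_fraction x the mean target (Yule
            # realizations otherwise occasionally put a pair inside the
            # within-species range, which is not the clean-signal design)
            h_min = 0.5 * cfg.min_inter_fraction * target
            for _ in range(8):
                m = _pairwise_mean(sp_tree_locus)
                sp_tree_locus.scale(target / m)
                _enforce_min_height(sp_tree_locus, h_min)

        # evolve: root -> species tips
        root_seq = rng.integers(0, 4, size=length).astype(np.int64)
        sp_tip_seqs = _evolve_tree(sp_tree_locus, root_seq, rate, cfg.kappa, rng)
        if S == 1:
            sp_tip_seqs = {species_names[0]: root_seq}

        seqs: dict[str, np.ndarray] = {}
        for sp in species_names:
            seqs.update(
                _evolve_tree(tufts[sp], sp_tip_seqs[sp], rate, cfg.kappa, rng)
            )

        # synonym references: identical copies of the species' reference seqs
        for sp, syn_name in synonym_groups:
            for src, dst in zip(ref_ids[sp], syn_ref_ids[syn_name]):
                seqs[dst] = seqs[src].copy()

        # discordant specimens: species membership depends on locus
        for sid, (sp_l0, sp_l1) in zip(discordant_ids, disc_species):
            sp = sp_l0 if locus_idx == 0 else sp_l1
            depth = tip_depth[sp]
            seqs[sid] = evolve_k80(
                sp_tip_seqs[sp], depth * rate, cfg.kappa, rng
            )

        # outgroup: evolve from the root at the configured extra depth
        if og_tree is not None:
            og_tip_depth = float(np.mean(list(_tip_depths(og_tree).values())))
            og_stem = max(
                cfg.outgroup_depth_multiplier * cfg.delta_inter * cfg.depth_multiplier
                - og_tip_depth,
                cfg.delta_inter * cfg.depth_multiplier / 2.0,
            )
            og_mrca_seq = evolve_k80(root_seq, og_stem * rate, cfg.kappa, rng)
            seqs.update(_evolve_tree(og_tree, og_mrca_seq, rate, cfg.kappa, rng))

        # assemble alignment: specimens first, then references, then outgroup
        ids, roles = [], {}
        for sid in specimen_ids:
            ids.append(sid)
            roles[sid] = "specimen"
        for sp in species_names:
            for rid in ref_ids[sp]:
                ids.append(rid)
                roles[rid] = "reference"
        for sp, syn_name in synonym_groups:
            for rid in syn_ref_ids[syn_name]:
                ids.append(rid)
                roles[rid] = "reference"
        for rid in og_ref_ids:
            ids.append(rid)
            roles[rid] = "outgroup"
        alignments.append(
            Alignment(
                ids=ids,
                sequences=[_decode(seqs[i]) for i in ids],
                locus_name=locus,
                roles=roles,
            )
        )

        # per-locus truth
        truth_locus = dict(species_of_regular)
        for sid, (sp_l0, sp_l1) in zip(discordant_ids, disc_species):
            truth_locus[sid] = sp_l0 if locus_idx == 0 else sp_l1
        for sid in og_specimen_ids:
            truth_locus[sid] = OUTGROUP_SPECIES
        species_by_locus.append(truth_locus)

        # reference rows
        acc = 0
        for sp in species_names:
            for rid in ref_ids[sp]:
                acc += 1
                reference_rows.append(
                    {"sequence_id": rid, "species": sp, "locus": locus,
                     "accession": f"SYN{locus_idx}{acc:04d}"}
                )
        for sp, syn_name in synonym_groups:
            for rid in syn_ref_ids[syn_name]:
                acc += 1
                reference_rows.append(
                    {"sequence_id": rid, "species": syn_name, "locus": locus,
                     "accession": f"SYN{locus_idx}{acc:04d}"}
                )
        for rid in og_ref_ids:
            acc += 1
            reference_rows.append(
                {"sequence_id": rid, "species": OUTGROUP_SPECIES, "locus": locus,
                 "accession": f"SYN{locus_idx}{acc:04d}"}
            )

    # --- metadata
    site_codes = [f"s{i + 1:02d}" for i in range(cfg.n_sites)]
    metadata = pd.DataFrame(
        {
            "specimen_id": specimen_ids,
            "site_code": [site_codes[int(i)] for i in rng.integers(0, cfg.n_sites, size=total_specimens)],
            "morphotype": ["" for _ in specimen_ids],
        }
    )

    final_truth: dict[str, str] = dict(species_of_regular)
    for sid in discordant_ids:
        final_truth[sid] = "discordant"
    for sid in og_specimen_ids:
        final_truth[sid] = OUTGROUP_SPECIES

    truth = GroundTruth(
        species_by_locus=species_by_locus,
        final_truth=final_truth,
        discordant_ids=list(discordant_ids),
        synonym_groups=synonym_groups,
        species_tree_newick=sp_tree.newick() + ";",
    )
    references = pd.DataFrame(
        reference_rows, columns=["sequence_id", "species", "locus", "accession"]
    )
    return SimulatedDataset(
        config=cfg,
        alignments=alignments,
        metadata=metadata,
        references=references,
        truth=truth,
    )


def _clone(node: _Node) -> _Node:
    new = _Node(node.label)
    new.blen = node.blen
    new.children = [_clone(c) for c in node.children]
    return new


def simulate_delimitation_tree(
    n_species: int,
    tips_per_species: int,
    tuft_depth: float,
    stem_depth: float,
    seed: int = 0,
):
    """Ultrametric gene tree with exact species structure, for GMYC validation.

    Each species' within-species genealogy is a Kingman coalescent rescaled so
    its MRCA sits exactly at ``tuft_depth``; species lineages then join under a
    Yule process starting at ``stem_depth``. The stem/tuft depth ratio is thus
    exactly ``stem_depth / tuft_depth``. Returns a dendropy tree whose true
    entity count is ``n_species``.
    """
    import dendropy

    rng = np.random.default_rng(seed)
    tufts = []
    for k in range(n_species):
        tuft = _kingman_tree(
            [f"sp{k + 1}_{i + 1}" for i in range(tips_per_species)], rng
        )
        depth = max(_tip_depths(tuft).values())
        if depth > 0:
            tuft.scale(tuft_depth / depth)
        tufts.append(tuft)
    # join tufts with Yule waits above stem_depth
    active = [(t, tuft_depth if tips_per_species > 1 else 0.0) for t in tufts]
    t = stem_depth
    while len(active) > 1:
        n = len(active)
        t += rng.exponential(1.0 / n) * stem_depth
        i, j = sorted(rng.choice(n, size=2, replace=False))
        parent = _Node()
        for k, (node, h) in ((i, active[i]), (j, active[j])):
            node.blen = t - h
            parent.children.append(node)
        active = [active[k] for k in range(n) if k not in (i, j)] + [(parent, t)]
    root = active[0][0]
    return dendropy.Tree.get(
        data=root.newick() + ";",
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


# -- frozen fixtures -------------------------------------------------------

FIXTURE_CONFIGS: dict[str, SimulationConfig] = {
    "clean": SimulationConfig(
        n_species=5,
        specimens_per_species=(6, 6, 6, 6, 6),
        outgroup_specimens=0,
        n_discordant=0,
        n_synonym_pairs=0,
        n_sites=6,
        locus_lengths=(600, 500),
        seed=101,
    ),
    "discordant": SimulationConfig(
        n_species=5,
        specimens_per_species=(6, 6, 6, 6, 6),
        outgroup_specimens=0,
        n_discordant=3,
        n_synonym_pairs=0,
        n_sites=6,
        locus_lengths=(600, 500),
        seed=202,
    ),
    "synonym": SimulationConfig(
        n_species=5,
        specimens_per_species=(6, 6, 6, 6, 6),
        outgroup_specimens=0,
        n_discordant=0,
        n_synonym_pairs=2,
        n_sites=6,
        locus_lengths=(600, 500),
        seed=303,
    ),
}


def frozen_fixture(name: str) -> SimulatedDataset:
    """One of the three frozen small datasets: clean, discordant, synonym."""
    if name not in FIXTURE_CONFIGS:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURE_CONFIGS)}")
    return simulate(FIXTURE_CONFIGS[name])
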