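"""Seeded synthetic-data generators for every pipeline stage.

Each generator takes an explicit seed and builds its own
``numpy.random.Generator``; identical arguments give bit-identical outputs
and every output satisfies the input contracts of the consuming module.
"""

from __future__ import annotations

import numpy as np

import dendropy

from .alignment import Alignment, BASES
from .dec import DECModelSpec, build_q, build_state_space, cladogenesis_splits
from .errors import ConfigError
from .likelihood import SubstitutionModel
from .shape import LandmarkConfig
from .trees import node_ages, read_newick


def sim_tree(n_taxa: int, root_age: float, seed: int = 0, birth_rate: float = 1.0) -> dendropy.Tree:
    """Ultrametric pure-birth (Yule) tree rescaled to the requested root age.

    Speciation times are simulated forward under a constant birth rate until
    ``n_taxa`` lineages exist, then the tree is rescaled so the root sits at
    ``root_age`` time units before the present.
    """
    if n_taxa < 2:
        raise ConfigError("need at least two taxa")
    rng = np.random.default_rng(seed)
    # event times: with k lineages the next split is Exp(k * birth_rate) later
    times = [0.0]
    t = 0.0
    for k in range(1, n_taxa):
        t += rng.exponential(1.0 / (k * birth_rate))
        times.append(t)
    total = times[-1] + rng.exponential(1.0 / (n_taxa * birth_rate))
    # the tree's root is the first split, at times[1]
    scale = root_age / (total - times[1])

    # build topology: maintain active lineage list; at each event split one
    children: dict[int, tuple[int, int]] = {}
    birth: dict[int, float] = {0: 0.0}
    active = [0]
    next_id = 1
    for et in times[1:]:
        i = int(rng.integers(len(active)))
        parent = active.pop(i)
        left, right = next_id, next_id + 1
        next_id += 2
        children[parent] = (left, right)
        birth[left] = birth[right] = et
        active.extend([left, right])

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    # edge length of a lineage = (its own split time, or the present) - birth
    def build2(node_id: int, dnode) -> None:
        if node_id in children:
            for c in children[node_id]:
                child = dendropy.Node()
                end = birth[children[c][0]] if c in children else total
                child.edge.length = (end - birth[c]) * scale
                dnode.add_child(child)
                build2(c, child)
        else:
            dnode.taxon = taxa.new_taxon(label=f"t{node_id}")

    root = tree.seed_node
    for c in children[0]:
        child = dendropy.Node()
        end = birth[children[c][0]] if c in children else total
        child.edge.length = (end - birth[c]) * scale
        root.add_child(child)
        build2(c, child)
    return tree


def sim_sequences(
    tree: dendropy.Tree,
    model: SubstitutionModel,
    length: int,
    seed: int = 0,
) -> Alignment:
    """Evolve sequences down a tree under TN93(+G+I).

    Branch lengths are expected substitutions per site.  Site rates are
    drawn once per site from the +G+I mixture and apply on every branch.
    """
    if not isinstance(tree, dendropy.Tree):
        tree = read_newick(tree)
    rng = np.random.default_rng(seed)
    q = model.q_matrix()
    rates, weights = model.category_rates()
    site_cat = rng.choice(len(rates), size=length, p=weights)
    site_rates = rates[site_cat]

    from scipy.linalg import expm

    root_states = rng.choice(4, size=length, p=model.freqs)
    seqs: dict[str, np.ndarray] = {}

    def walk(node, states: np.ndarray) -> None:
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            new = states.copy()
            if t > 0:
                for rate in np.unique(site_rates):
                    if rate == 0:
                        continue
                    p = expm(q * (rate * t))
                    cum = p.cumsum(axis=1)
                    sel = site_rates == rate
                    u = rng.random(sel.sum())
                    old = states[sel]
                    new_states = (u[:, None] > cum[old]).sum(axis=1)
                    new[sel] = new_states
            if child.is_leaf():
                seqs[child.taxon.label] = new
            walk(child, new)

    walk(tree.seed_node, root_states)
    base_arr = np.array(list(BASES))
    ids = [lf.taxon.label for lf in tree.leaf_node_iter()]
    mat = np.stack([base_arr[seqs[i]] for i in ids])
    return Alignment(ids=ids, matrix=mat)


def sim_dec_history(
    chronogram: dendropy.Tree,
    spec: DECModelSpec,
    d: float,
    e: float,
    seed: int = 0,
    root_range: frozenset | None = None,
    keep_extinct: bool = False,
    max_tries: int = 1000,
):
    """Forward (Gillespie) simulation of a DEC range history.

    Returns ``(tip_ranges, events, node_ranges)``: observed ranges per tip
    label, the anagenetic event log (lineage, time, from-range, to-range),
    and the true range at every internal node.  By default replicates in
    which any lineage goes globally extinct are redrawn (conditioning on all
    tips surviving); ``keep_extinct=True`` returns them as-is with extinct
    tips mapped to the empty range.
    """
    rng = np.random.default_rng(seed)
    states = build_state_space(spec)
    index = {s: i for i, s in enumerate(states)}
    ages = node_ages(chronogram)
    prior_states = [s for s in states if s]

    for _ in range(max_tries):
        extinct = False
        tip_ranges: dict[str, frozenset] = {}
        node_ranges: dict = {}
        events: list[tuple[str, float, frozenset, frozenset]] = []

        root_state = root_range if root_range is not None else prior_states[
            rng.integers(len(prior_states))
        ]
        node_ranges[chronogram.seed_node] = root_state

        def evolve(state: frozenset, t_old: float, t_young: float, label: str):
            nonlocal extinct
            t = t_old
            while t > t_young and state:
                # epoch active at time t
                epoch = None
                for ep in spec.epochs:
                    if ep.start < t <= ep.end + 1e-12:
                        epoch = ep
                        break
                q = build_q(spec, d, e, epoch)
                i = index[state]
                total_rate = -q[i, i]
                if total_rate <= 0:
                    break
                wait = rng.exponential(1.0 / total_rate)
                t_next = t - wait
                # epoch boundary between t and t_next? restart draw from boundary
                if epoch is not None and t_next < epoch.start and epoch.start > t_young:
                    t = epoch.start
                    continue
                if t_next <= t_young:
                    break
                probs = q[i].copy()
                probs[i] = 0
                probs = probs / probs.sum()
                j = rng.choice(len(states), p=probs)
                events.append((label, t_next, state, states[j]))
                state = states[j]
                t = t_next
            if not state:
                extinct = True
            return state

        def _recurse_split(node, daughter_states) -> None:
            for child, st in zip(node.child_nodes(), daughter_states):
                child_state = evolve(
                    st, ages[node], max(ages[child], 0.0),
                    label=child.taxon.label if child.is_leaf() else f"node{id(child)}",
                )
                if child.is_leaf():
                    tip_ranges[child.taxon.label] = child_state
                else:
                    if child_state:
                        splits = cladogenesis_splits(child_state, spec)
                        weights = np.array([w for _, _, w in splits])
                        pick = rng.choice(len(splits), p=weights / weights.sum())
                        node_ranges[child] = child_state
                        _recurse_split(child, splits[pick][:2])
                    else:
                        node_ranges[child] = child_state
                        _mark_extinct(child)

        def _mark_extinct(node) -> None:
            nonlocal extinct
            extinct = True
            for lf in node.leaf_iter():
                tip_ranges[lf.taxon.label] = frozenset()

        # root cladogenesis
        splits = cladogenesis_splits(root_state, spec)
        weights = np.array([w for _, _, w in splits])
        pick = rng.choice(len(splits), p=weights / weights.sum())
        _recurse_split(chronogram.seed_node, splits[pick][:2])

        if extinct and not keep_extinct:
            continue
        return tip_ranges, events, node_ranges
    raise RuntimeError(
        f"no surviving replicate in {max_tries} tries (e too high?)"
    )


def sim_landmarks(
    mean_shape: np.ndarray,
    n_per_group: dict[str, int],
    group_displacement: dict[str, np.ndarray],
    noise_sd: float,
    seed: int = 0,
    n_replicates: int = 1,
) -> list[LandmarkConfig]:
    """Landmark configurations: mean shape + group displacement + iid noise.

    Displacements are (k, 2) shape offsets added to the mean; each specimen
    gets ``n_replicates`` noisy re-digitizations (replicate noise drawn
    independently), emulating repeat photography of the same skull.
    """
    rng = np.random.default_rng(seed)
    mean_shape = np.asarray(mean_shape, dtype=float)
    out = []
    for group, n in n_per_group.items():
        disp = np.asarray(group_displacement.get(group, 0.0), dtype=float)
        for i in range(n):
            specimen_shape = mean_shape + disp + rng.normal(
                0, noise_sd, size=mean_shape.shape
            )
            for rep in range(n_replicates):
                coords = specimen_shape + rng.normal(
                    0, noise_sd / 3 if n_replicates > 1 else 0.0,
                    size=mean_shape.shape,
                )
                out.append(
                    LandmarkConfig(
                        coords=coords,
                        specimen=f"{group}_{i}",
                        replicate=rep,
                        group=group,
                    )
                )
    return out


def sim_specimens(
    group_means: dict[str, float],
    group_sds: dict[str, float],
    ns: dict[str, int],
    seed: int = 0,
):
    """Body-weight records for several groups (normal weights, floored at 1 g)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for group, n in ns.items():
        w = rng.normal(group_means[group], group_sds[group], size=n)
        w = np.maximum(w, 1.0)
        for i, wi in enumerate(w):
            rows.append(
                {
                    "species": group,
                    "sample_qmul": f"{group}_{i}",
                    "sex": "M" if rng.random() < 0.5 else "F",
                    "body_weight_g": float(wi),
                    "age_class": int(rng.integers(2, 5)),
                }
            )
    return pd.DataFrame(rows)
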