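import numpy as np
import pytest

from svorigin import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A small, cleanly separated cohort shared by read-only tests."""
    cfg = synthetic.CohortConfig(
        n_wild_yak=6,
        n_domestic_yak=8,
        n_cattle=6,
        n_outgroup=2,
        n_snps_per_window=300,
        n_sv_loci=8,
        seed=11,
    )
    return synthetic.simulate_cohort(cfg)


@pytest.fixture
def planted_filter_vcf(tmp_path):
    """Toy VCF with known filter outcomes for 10 diploid samples.

    v1: full call rate, MAF 0.30          -> retained
    v2: call rate 0.8, MAF 0.30           -> retained
    v3: call rate 0.6                     -> dropped (call_rate)
    v4: monomorphic reference (MAF 0)     -> dropped (maf)
    v5: singleton alt, MAF exactly 0.05   -> retained (not < 0.05)
    v6: monomorphic alternate (MAF 0)     -> dropped (maf)
    """
    samples = [f"s{i}" for i in range(10)]
    gts = {
        "v1": ["0/1"] * 6 + ["0/0"] * 4,
        "v2": ["./."] * 2 + ["0/1"] * 6 + ["0/0"] * 2,
        "v3": ["./."] * 4 + ["0/1"] * 4 + ["0/0"] * 2,
        "v4": ["0/0"] * 10,
        "v5": ["0/1"] + ["0/0"] * 9,
        "v6": ["1/1"] * 10,
    }
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=chr1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for i, (vid, row) in enumerate(gts.items(), start=1):
        lines.append(
            f"chr1\t{i * 100}\t{vid}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(row)
        )
    path = tmp_path / "planted.vcf"
    path.write_text("\n".join(lines) + "\n")
    return path


def random_tree_distances(n_taxa: int, rng: np.random.Generator):
    """Random binary tree on n_taxa leaves; return (distance matrix, splits).

    Built by sequential attachment: each new leaf is grafted onto a
    uniformly chosen existing edge, giving an additive distance matrix and
    the tree's non-trivial bipartitions (as frozensets of leaf names).
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # adjacency: node -> list of (node, length); leaves are labels,
    # internal nodes are ints
    adj = {labels[0]: [], labels[1]: []}
    next_internal = 0

    def add_edge(a, b, length):
        adj.setdefault(a, []).append((b, length))
        adj.setdefault(b, []).append((a, length))

    def del_edge(a, b):
        adj[a] = [(x, l) for x, l in adj[a] if x != b]
        adj[b] = [(x, l) for x, l in adj[b] if x != a]

    add_edge(labels[0], labels[1], float(rng.uniform(0.5, 2.0)))
    edges = [(labels[0], labels[1])]
    for leaf in labels[2:]:
        a, b = edges[rng.integers(len(edges))]
        length = dict(adj[a])[b]
        mid = next_internal
        next_internal += 1
        del_edge(a, b)
        cut = float(rng.uniform(0.25, 0.75)) * length
        add_edge(a, mid, cut)
        add_edge(mid, b, length - cut)
        add_edge(mid, leaf, float(rng.uniform(0.5, 2.0)))
        edges.remove((a, b))
        edges += [(a, mid), (mid, b), (mid, leaf)]

    # leaf-to-leaf path distances by BFS
    dist = np.zeros((n_taxa, n_taxa))
    for i, src in enumerate(labels):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nb, length in adj[cur]:
                if nb not in seen:
                    seen[nb] = seen[cur] + length
                    stack.append(nb)
        for j, dst in enumerate(labels):
            dist[i, j] = seen[dst]

    # bipartitions: removing each internal-internal or internal-leaf edge
    all_leaves = frozenset(labels)
    splits = set()
    for a, b in edges:
        side = set()
        stack = [a]
        seen = {a, b}
        while stack:
            cur = stack.pop()
            if isinstance(cur, str):
                side.add(cur)
            for nb, _ in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        side = frozenset(side)
        if 1 < len(side) < n_taxa - 1:
            splits.add(min(side, all_leaves - side, key=sorted))
    return dist, labels, splits
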