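"""Brute-force consolidation oracle: direct rule application, no shared code.

Used by the unit suite and the acceptance suite to cross-check the
distance-grouping + LD-merging + gene-merging pipeline on random
instances.
"""

import itertools

import numpy as np
import pandas as pd

from eqtlkit.eqtl_calling import snp_r2


def oracle_consolidate(sig, table, annotation, min_snps=3, gap=5000,
                        r2_min=0.1, max_dist=250000):
    """Direct rule application with no shared code paths."""
    if len(sig) < min_snps:
        return []
    order = sig.sort_values(["chrom", "pos"]).index.tolist()
    clusters = [[order[0]]]
    for prev, cur in zip(order, order[1:]):
        same = sig.loc[prev, "chrom"] == sig.loc[cur, "chrom"]
        if same and sig.loc[cur, "pos"] - sig.loc[prev, "pos"] < gap:
            clusters[-1].append(cur)
        else:
            clusters.append([cur])

    def lead(members):
        sub = sig.loc[members]
        return sub.sort_values(["p", "partial_r2", "pos"],
                               ascending=[True, False, True]).index[0]

    import itertools

    def components(items, related):
        """Connected components by breadth-first search.

        ``related`` compares the per-phase leads, which are fixed while a
        phase runs, so they are computed once up front.
        """
        leads = [sig.loc[lead(c)] for c in items]
        adj = {i: set() for i in range(len(items))}
        for i, j in itertools.combinations(range(len(items)), 2):
            if related(leads[i], leads[j]):
                adj[i].add(j)
                adj[j].add(i)
        seen, comps = set(), []
        for i in range(len(items)):
            if i in seen:
                continue
            stack, comp = [i], []
            while stack:
                k = stack.pop()
                if k in seen:
                    continue
                seen.add(k)
                comp.append(k)
                stack.extend(adj[k] - seen)
            comps.append(sorted(comp))
        return [sum((items[k] for k in comp), []) for comp in comps]

    # transitive LD merge over the pre-merge cluster leads
    def ld_related(a, b):
        if a["chrom"] != b["chrom"] or abs(int(a["pos"]) - int(b["pos"])) > max_dist:
            return False
        return snp_r2(table, a["snp"], b["snp"]) > r2_min

    clusters = components(clusters, ld_related)

    # gene-containment merge over the post-LD cluster leads
    def gene_related(a, b):
        ga = set(annotation.genes_containing(a["chrom"], int(a["pos"])))
        gb = set(annotation.genes_containing(b["chrom"], int(b["pos"])))
        return bool(ga & gb)

    clusters = components(clusters, gene_related)
    return sorted(
        (tuple(sorted(sig.loc[m, "snp"] for m in c)), sig.loc[lead(c), "snp"])
        for c in clusters
    )




def random_instance(rng, max_snps=25, n_samples=20, span=300000):
    """A random significant-SNP frame plus matching genotype table."""
    from conftest import make_table

    m = int(rng.integers(3, max_snps))
    pos = np.sort(rng.choice(np.arange(1, span), size=m, replace=False))
    calls = rng.choice([0, 2], size=(n_samples, m), p=[0.5, 0.5])
    for j in range(1, m):
        if rng.uniform() < 0.4:
            calls[:, j] = calls[:, j - 1]
    table = make_table(calls.astype(np.int8).tolist(), pos=pos.tolist())
    sig = pd.DataFrame(
        {"snp": [f"s{j}" for j in range(m)], "chrom": ["1"] * m, "pos": pos,
         "p": 10.0 ** -rng.uniform(6, 12, size=m),
         "partial_r2": rng.uniform(0.05, 0.4, size=m)}
    )
    return sig, table
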