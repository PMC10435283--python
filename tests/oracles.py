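"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's algorithmic code paths: chain search
is an exhaustive depth-first enumeration of maximal monotone chains,
colocalization is an all-pairs scan, and ontology closure is computed by
repeated squaring of the boolean reachability matrix.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# Exhaustive monotone-chain oracle
# ---------------------------------------------------------------------------


def _collapse_tandems(genes, og_of):
    """(rank, gene_id) for chaining, dropping consecutive same-group genes."""
    out = []
    prev = None
    for rank, gid in enumerate(genes):
        group = og_of.get(gid)
        if group is not None and group == prev:
            prev = group
            continue
        prev = group
        if group is not None:
            out.append((rank, gid))
    return out


def _matches(chrom_a, genes_a, chrom_b, genes_b, og_of):
    ra_list = _collapse_tandems(genes_a, og_of)
    rb_list = _collapse_tandems(genes_b, og_of)
    self_pair = chrom_a == chrom_b
    matches = []
    for ra, ga in ra_list:
        for rb, gb in rb_list:
            if og_of[ga] != og_of[gb] or ga == gb:
                continue
            if self_pair and rb <= ra:
                continue
            matches.append((ra, rb, ga, gb))
    return matches


def _enumerate_maximal_chains(matches, orientation, max_gap):
    """All maximal admissible chains, by exhaustive DFS."""

    def can_follow(m1, m2):
        da, db = m2[0] - m1[0], m2[1] - m1[1]
        if not (0 < da <= max_gap):
            return False
        if orientation == "plus":
            return 0 < db <= max_gap
        return 0 < -db <= max_gap

    chains = []

    def extend(chain):
        extended = False
        for m in matches:
            if can_follow(chain[-1], m):
                extended = True
                extend(chain + [m])
        if not extended:
            chains.append(chain)

    for m in matches:
        extend([m])
    return chains


def exhaustive_blocks(gene_orders, og_of, min_genes, max_gap):
    """Greedy longest-first block extraction with full chain enumeration.

    ``gene_orders``: chromosome -> ordered gene ID list.  Returns blocks as
    (chromosome_a, chromosome_b, orientation, tuple of gene-ID pairs), in
    extraction order, matching the documented tie-break rules.
    """
    blocks = []
    chroms = sorted(gene_orders)
    for ia, chrom_a in enumerate(chroms):
        for chrom_b in chroms[ia:]:
            pool = _matches(
                chrom_a, gene_orders[chrom_a], chrom_b, gene_orders[chrom_b], og_of
            )
            while pool:
                candidates = []
                for orient_rank, orientation in enumerate(("plus", "minus")):
                    for chain in _enumerate_maximal_chains(pool, orientation, max_gap):
                        if len(chain) < min_genes:
                            continue
                        seq = tuple((m[0], m[1]) for m in chain)
                        key = (-len(chain), chain[0][0], orient_rank, seq)
                        candidates.append((key, orientation, chain))
                if not candidates:
                    break
                _, orientation, chain = min(candidates, key=lambda c: c[0])
                blocks.append(
                    (
                        chrom_a,
                        chrom_b,
                        orientation,
                        tuple((m[2], m[3]) for m in chain),
                    )
                )
                used = {(m[2], m[3]) for m in chain}
                pool = [m for m in pool if (m[2], m[3]) not in used]
    return blocks


# ---------------------------------------------------------------------------
# All-pairs colocalization oracle
# ---------------------------------------------------------------------------


def allpairs_colocalize(genes, qtls, gwas_window=0):
    """``genes``: (gene_id, chromosome, start, end).  ``qtls``: QTLRecord-like
    objects.  Returns (relation, gene_id, qtl_id, distance-or-None) tuples in
    the same order as the implementation contract: per QTL, colocalizations
    sorted by gene ID, then the closest-to-peak link."""
    out = []
    chroms = {g[1] for g in genes}
    for qtl in qtls:
        if qtl.chromosome not in chroms:
            continue
        if qtl.interval is not None:
            lo, hi = qtl.interval
        else:
            lo, hi = qtl.peak - gwas_window, qtl.peak + gwas_window
        hits = sorted(
            g[0]
            for g in genes
            if g[1] == qtl.chromosome and g[3] >= lo and g[2] <= hi
        )
        for gid in hits:
            out.append(("COLOCALIZES_WITH", gid, qtl.qtl_id, None))
        if qtl.peak is not None:
            on_chrom = [g for g in genes if g[1] == qtl.chromosome]
            if on_chrom:
                def dist(g):
                    if g[2] <= qtl.peak <= g[3]:
                        return 0
                    return min(abs(qtl.peak - g[2]), abs(qtl.peak - g[3]))

                best = min(on_chrom, key=lambda g: (dist(g), g[2], g[0]))
                out.append(("IS_CLOSEST_TO_PEAK", best[0], qtl.qtl_id, dist(best)))
    return out


# ---------------------------------------------------------------------------
# Reachability-closure oracle
# ---------------------------------------------------------------------------


def closure_descendants(terms, edges, root):
    """Reflexive descendants of ``root`` over child->parent ``edges``,
    via repeated squaring of the boolean adjacency matrix."""
    idx = {t: i for i, t in enumerate(sorted(terms))}
    n = len(idx)
    reach = np.eye(n, dtype=bool)
    for child, parent in edges:
        reach[idx[child], idx[parent]] = True
    while True:
        nxt = reach | (reach @ reach)
        if (nxt == reach).all():
            break
        reach = nxt
    r = idx[root]
    inv = {i: t for t, i in idx.items()}
    return {inv[i] for i in range(n) if reach[i, r]}
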