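"""Numba kernels for the forward-in-time simulator.

The hot loop is gamete assembly: for every meiosis, crossover positions are
drawn upstream (Poisson count per chromosome, uniform positions; Haldane, no
interference) and the kernel walks the locus list switching between the two
parental haplotypes at each crossover.  All randomness is generated outside
with a seeded numpy Generator so the kernels are pure functions.
"""

import numpy as np
from numba import njit

_MAX_XO = 64  # crossovers per chromosome per meiosis; Poisson(1) never nears this


@njit(cache=True)
def make_gametes(parent_haps, parent_ids, coin, n_xo, xo_pos, xo_off,
                 locus_pos, chrom_bounds, out):
    """Assemble gametes from parental haplotype pairs.

    parent_haps : (P, 2, L) int32 haplotypes of the parent generation
    parent_ids  : (G,) index of the parent contributing each gamete
    coin        : (G, C) starting haplotype (0/1) per gamete and chromosome
    n_xo        : (G, C) crossover counts
    xo_pos      : flat array of crossover positions (cM within chromosome)
    xo_off      : (G*C + 1,) offsets into xo_pos, row-major over (gamete, chrom)
    locus_pos   : (L,) locus positions in cM within chromosome
    chrom_bounds: (C + 1,) locus index bounds per chromosome
    out         : (G, L) int32 output gametes
    """
    G = out.shape[0]
    C = chrom_bounds.shape[0] - 1
    xs = np.empty(_MAX_XO, dtype=np.float64)
    for g in range(G):
        ph = parent_haps[parent_ids[g]]
        for c in range(C):
            k = n_xo[g, c]
            base = xo_off[g * C + c]
            for t in range(k):  # insertion sort (k is tiny)
                v = xo_pos[base + t]
                j = t
                while j > 0 and xs[j - 1] > v:
                    xs[j] = xs[j - 1]
                    j -= 1
                xs[j] = v
            src = coin[g, c]
            xi = 0
            for l in range(chrom_bounds[c], chrom_bounds[c + 1]):
                pos = locus_pos[l]
                while xi < k and xs[xi] <= pos:
                    src ^= 1
                    xi += 1
                out[g, l] = ph[src, l]
    return out


@njit(cache=True)
def genotype_codes(haps, chosen, locus_idx, out):
    """Signed genotype codes for the selected loci.

    haps      : (n, 2, L) int32
    chosen    : (L,) allele label that counts as allele 1 (0 = none)
    locus_idx : (M,) indices of the loci to emit
    out       : (n, M) int8, -1/0/+1 = 0, 1 or 2 copies of allele 1
    """
    n = haps.shape[0]
    M = locus_idx.shape[0]
    for j in range(M):
        l = locus_idx[j]
        a1 = chosen[l]
        if a1 == 0:
            for i in range(n):
                out[i, j] = -1
            continue
        for i in range(n):
            d = 0
            if haps[i, 0, l] == a1:
                d += 1
            if haps[i, 1, l] == a1:
                d += 1
            out[i, j] = d - 1
    return out
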