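"""Numba kernels for gamete formation.

The hot loop of the whole simulator: copying alleles from alternating
parental haplotypes between crossover breakpoints. Kept free of any RNG so
that all randomness stays in numpy Generators owned by the caller.
"""

import numba
import numpy as np


@numba.njit(cache=True)
def gamete_fill(haplo, parent_rows, chrom_starts, site_pos,
                co_pos, co_offsets, start_phase, out):
    """Fill ``out`` (g, S) with gametes.

    haplo        : (n, 2, S) uint8 parental haplotypes
    parent_rows  : (g,) row index of the transmitting parent per gamete
    chrom_starts : (C+1,) site-index boundaries per chromosome
    site_pos     : (S,) map positions in Morgans, sorted within chromosome
    co_pos       : flat crossover positions; slice [co_offsets[k*C+c],
                   co_offsets[k*C+c+1]) belongs to gamete k, chromosome c
                   (unsorted; sorted in place here)
    start_phase  : (g*C,) uint8, haplotype carried at position 0
    """
    g = parent_rows.shape[0]
    n_chrom = chrom_starts.shape[0] - 1
    for k in range(g):
        p = parent_rows[k]
        for c in range(n_chrom):
            b = co_offsets[k * n_chrom + c]
            e = co_offsets[k * n_chrom + c + 1]
            # insertion sort: crossover counts per chromosome are tiny
            for i in range(b + 1, e):
                v = co_pos[i]
                j = i - 1
                while j >= b and co_pos[j] > v:
                    co_pos[j + 1] = co_pos[j]
                    j -= 1
                co_pos[j + 1] = v
            phase = start_phase[k * n_chrom + c]
            jj = b
            for s in range(chrom_starts[c], chrom_starts[c + 1]):
                pos = site_pos[s]
                while jj < e and co_pos[jj] <= pos:
                    phase = 1 - phase
                    jj += 1
                out[k, s] = haplo[p, phase, s]
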