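"""Numba kernels for the founder-mosaic population representation.

Each haplotype is stored as a run-length track over the chromosome:
``seg_end[r, i]`` is the (1-based, inclusive) bp end of segment ``i`` of
haplotype row ``r`` and ``seg_org[r, i]`` the founder-haplotype index that
segment was copied from.  The last segment of every track ends at the
chromosome length.  Individual ``k`` owns haplotype rows ``2k`` and
``2k + 1``.  Per-generation work is proportional to N x (segments per
haplotype) rather than N x SNPs, which is what makes large-N, many-replicate
experiments affordable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

OVERFLOW = -1


@njit(cache=True)
def _copy_gamete(seg_end, seg_org, n_seg, hap_a, hap_b, cuts, c0, c1, start,
                 out_end, out_org, out_row, cap, chrom_len):
    """Build one gamete as the alternating mosaic of parent haplotype rows
    ``hap_a``/``hap_b`` with crossover cut positions ``cuts[c0:c1]`` (sorted,
    bp; a cut at c places positions <= c before the switch).  Returns the
    segment count or OVERFLOW if the output capacity is exceeded."""
    h = start
    ia = 0
    ib = 0
    m = 0
    pos = 0
    nc = c1 - c0
    for ci in range(nc + 1):
        cut = cuts[c0 + ci] if ci < nc else chrom_len
        if cut <= pos:
            h = 1 - h
            continue
        src = hap_a if h == 0 else hap_b
        i = ia if h == 0 else ib
        while seg_end[src, i] <= pos:
            i += 1
        while pos < cut:
            send = seg_end[src, i]
            e = send if send < cut else cut
            o = seg_org[src, i]
            if m > 0 and out_org[out_row, m - 1] == o:
                out_end[out_row, m - 1] = e
            else:
                if m >= cap:
                    return OVERFLOW
                out_end[out_row, m] = e
                out_org[out_row, m] = o
                m += 1
            pos = e
            if send == e and pos < cut:
                i += 1
        if h == 0:
            ia = i
        else:
            ib = i
        h = 1 - h
    return m


@njit(cache=True)
def next_generation_kernel(seg_end, seg_org, n_seg,
                           mothers, fathers, m_start, f_start,
                           m_cuts, m_off, f_cuts, f_off,
                           out_end, out_org, out_nseg, chrom_len):
    """Fill the offspring track arrays: child i gets a maternal gamete from
    individual ``mothers[i]`` and a paternal gamete from ``fathers[i]``.
    Returns 0, or OVERFLOW if the segment capacity was exceeded."""
    n = mothers.shape[0]
    cap = out_end.shape[1]
    for i in range(n):
        mi = mothers[i]
        m = _copy_gamete(seg_end, seg_org, n_seg, 2 * mi, 2 * mi + 1,
                         m_cuts, m_off[i], m_off[i + 1], m_start[i],
                         out_end, out_org, 2 * i, cap, chrom_len)
        if m == OVERFLOW:
            return OVERFLOW
        out_nseg[2 * i] = m
        fi = fathers[i]
        m = _copy_gamete(seg_end, seg_org, n_seg, 2 * fi, 2 * fi + 1,
                         f_cuts, f_off[i], f_off[i + 1], f_start[i],
                         out_end, out_org, 2 * i + 1, cap, chrom_len)
        if m == OVERFLOW:
            return OVERFLOW
        out_nseg[2 * i + 1] = m
    return 0


@njit(cache=True)
def genotypes_at_kernel(seg_end, seg_org, n_seg, target_pos, target_snp,
                        alleles, out):
    """Per-individual derived-allele counts at target SNPs.

    ``out`` has shape (N, n_targets); haplotype rows 2k, 2k+1 belong to
    individual k."""
    n_hap_rows = n_seg.shape[0]
    nt = target_pos.shape[0]
    for r in range(n_hap_rows):
        for t in range(nt):
            p = target_pos[t]
            i = 0
            while seg_end[r, i] < p:
                i += 1
            out[r // 2, t] += alleles[seg_org[r, i], target_snp[t]]


@njit(cache=True)
def decode_counts_kernel(seg_end, seg_org, n_seg, snp_pos, alleles, out_counts):
    """Accumulate per-SNP derived-allele counts over all haplotype rows.

    Segment i of row r covers positions (prev_end, seg_end] so each SNP is
    attributed to exactly one founder origin."""
    n_hap_rows = n_seg.shape[0]
    for r in range(n_hap_rows):
        idx0 = 0
        for i in range(n_seg[r]):
            end = seg_end[r, i]
            idx1 = np.searchsorted(snp_pos, end, side="right")
            org = seg_org[r, i]
            for j in range(idx0, idx1):
                out_counts[j] += alleles[org, j]
            idx0 = idx1
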