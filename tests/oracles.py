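"""Independent reference implementations used to cross-check the package.

Each oracle deliberately takes the most direct route — explicit enumeration,
whole-sequence rebuilding, all-pairs counting — and shares no code with the
implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Seq import Seq

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_force_site_keys(transcript, genome) -> set[tuple]:
    """Junction flank positions by direct per-exon arithmetic.

    Lists candidate positions for every UTR-trimmed exon, filtered by
    transcript-orientation first/last flags, without any shared helper.
    Returns {(contig, pos, strand, role, offset, ref_base_coding)}.
    """
    # UTR trimming by direct intersection
    trimmed = []
    for es, ee in sorted(transcript.exons):
        pieces = [
            (max(es, cs), min(ee, ce))
            for cs, ce in transcript.cds
            if max(es, cs) < min(ee, ce)
        ]
        if pieces:
            trimmed.append((min(p[0] for p in pieces), max(p[1] for p in pieces)))
    trimmed.sort()
    if not trimmed:
        return set()
    seq = genome[transcript.contig]
    out = set()
    n = len(trimmed)
    for i, (s, e) in enumerate(trimmed):
        length = e - s
        if transcript.strand == "+":
            genomic_first, genomic_last = (i == 0), (i == n - 1)
        else:
            genomic_first, genomic_last = (i == n - 1), (i == 0)
        for k in (1, 2, 3):
            if k > length:
                continue
            if transcript.strand == "+":
                donor_pos, acceptor_pos = e - k, s + k - 1
            else:
                donor_pos, acceptor_pos = s + k - 1, e - k
            if not genomic_last:
                base = str(seq[donor_pos]).upper()
                if transcript.strand == "-":
                    base = _COMP[base]
                out.add(
                    (transcript.contig, donor_pos, transcript.strand, "donor", k, base)
                )
            if not genomic_first:
                base = str(seq[acceptor_pos]).upper()
                if transcript.strand == "-":
                    base = _COMP[base]
                out.add(
                    (
                        transcript.contig,
                        acceptor_pos,
                        transcript.strand,
                        "acceptor",
                        k,
                        base,
                    )
                )
    return out


def protein_consequence(transcript, genome, position: int, ref: str, alt: str) -> str:
    """Consequence by rebuilding the whole spliced CDS and comparing proteins."""
    seq = str(genome[transcript.contig]) if not isinstance(genome[transcript.contig], str) else genome[transcript.contig]
    cds_positions = []
    for s, e in sorted(transcript.cds):
        cds_positions.extend(range(s, e))
    assert position in cds_positions
    ref_seq = "".join(seq[p] for p in cds_positions)
    idx = cds_positions.index(position)
    assert ref_seq[idx].upper() == ref.upper()
    alt_seq = ref_seq[:idx] + alt + ref_seq[idx + 1 :]
    if transcript.strand == "-":
        ref_seq = str(Seq(ref_seq).reverse_complement())
        alt_seq = str(Seq(alt_seq).reverse_complement())
        idx = len(ref_seq) - 1 - idx
    ref_protein = str(Seq(ref_seq).translate())
    alt_protein = str(Seq(alt_seq).translate())
    codon_idx = idx // 3
    if ref_protein[codon_idx] == "*":
        return "other"  # convention: variants in reference stop codons
    if alt_protein[codon_idx] == "*":
        return "nonsense"
    diffs = [i for i, (a, b) in enumerate(zip(ref_protein, alt_protein)) if a != b]
    return "silent" if not diffs else "missense"


def auc_pair_counting(scores, labels) -> float:
    """All-pairs concordance with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact P[X >= k] by summing the combinatorial pmf."""
    denom = math.comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


def kruskal_h(groups) -> float:
    """Tie-corrected Kruskal-Wallis H from first principles (midranks)."""
    pooled = [v for g in groups for v in g]
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        midrank = (i + j + 1) / 2.0
        for idx in order[i:j]:
            ranks[idx] = midrank
        i = j
    n = len(pooled)
    offset = 0
    h = 0.0
    for g in groups:
        r = sum(ranks[offset : offset + len(g)])
        h += r * r / len(g)
        offset += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    ties = 0
    values = sorted(pooled)
    i = 0
    while i < n:
        j = i
        while j < n and values[j] == values[i]:
            j += 1
        t = j - i
        ties += t**3 - t
        i = j
    correction = 1 - ties / (n**3 - n)
    return h / correction if correction > 0 else 0.0


def kruskal_permutation_p(groups, n_perm: int = 20000, seed: int = 0) -> float:
    """Permutation null of the Kruskal-Wallis H statistic."""
    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    pooled = np.array([v for g in groups for v in g], dtype=float)
    observed = kruskal_h(groups)
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        perm_groups = []
        offset = 0
        for size in sizes:
            perm_groups.append(pooled[offset : offset + size].tolist())
            offset += size
        if kruskal_h(perm_groups) >= observed - 1e-12:
            count += 1
    return count / n_perm


def reflect_locus(contigs: dict[str, str], transcripts):
    """Reverse-complement every contig and flip all coordinates and strands."""
    import copy

    new_contigs = {
        name: str(Seq(seq).reverse_complement()) for name, seq in contigs.items()
    }
    new_transcripts = []
    for t in transcripts:
        L = len(contigs[t.contig])
        nt = copy.deepcopy(t)
        nt.strand = "-" if t.strand == "+" else "+"
        nt.exons = sorted((L - e, L - s) for s, e in t.exons)
        nt.cds = sorted((L - e, L - s) for s, e in t.cds)
        new_transcripts.append(nt)
    return new_contigs, new_transcripts
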