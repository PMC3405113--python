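"""Haploid coalescent with recombination (Hudson's algorithm).

Simulates the ancestral recombination graph of ``n`` haploid samples
backwards in time, tracking for every lineage the genomic segments that
are ancestral to the sample together with the bitmask of samples each
segment subtends.  Mutations are dropped as a Poisson process on the
live ancestral material, so each mutation yields the set of carriers
directly, under an infinite-sites model on a continuous coordinate that
is later snapped to the integer grid.

Time is measured in units of N generations (haploid population of size
N), so a pair of lineages coalesces at rate 1 and the per-base mutation
and recombination rates on a lineage are theta/2 and rho/2 with
theta = 2*N*mu and rho = 2*N*r.

A two-population split is supported: more recently than ``split_depth``
lineages coalesce only within their own subpopulation; at the split the
populations merge into the ancestral one.
"""

from __future__ import annotations

import numpy as np

__all__ = ["simulate_mutations", "PositionsExhausted", "assign_integer_positions"]


class PositionsExhausted(RuntimeError):
    """More mutations than integer positions; use a longer chromosome."""


# a lineage is (population, segments); segments is a sorted,
# non-overlapping list of (start, end, carrier_mask) half-open intervals


def _span(segments: list[tuple[float, float, int]]) -> float:
    return segments[-1][1] - segments[0][0]


def _length(segments: list[tuple[float, float, int]]) -> float:
    return sum(e - s for s, e, _ in segments)


def _merge_segments(a, b, full_mask):
    """Union of two carrier-interval lists; fully coalesced spans dropped."""
    bounds = sorted({x for s, e, _ in a for x in (s, e)}
                    | {x for s, e, _ in b for x in (s, e)})
    out: list[tuple[float, float, int]] = []
    ia = ib = 0
    for lo, hi in zip(bounds, bounds[1:]):
        m = 0
        while ia < len(a) and a[ia][1] <= lo:
            ia += 1
        if ia < len(a) and a[ia][0] <= lo:
            m |= a[ia][2]
        while ib < len(b) and b[ib][1] <= lo:
            ib += 1
        if ib < len(b) and b[ib][0] <= lo:
            m |= b[ib][2]
        if m and m != full_mask:
            if out and out[-1][1] == lo and out[-1][2] == m:
                out[-1] = (out[-1][0], hi, m)
            else:
                out.append((lo, hi, m))
    return out


def _split_segments(segments, breakpoint):
    left = []
    right = []
    for s, e, m in segments:
        if e <= breakpoint:
            left.append((s, e, m))
        elif s >= breakpoint:
            right.append((s, e, m))
        else:
            left.append((s, breakpoint, m))
            right.append((breakpoint, e, m))
    return left, right


def _drop_mutations(lineages, lengths, total_len, theta_per_base, dt, rng, out):
    """Poisson mutations over a dt interval of constant lineage state."""
    lam = 0.5 * theta_per_base * total_len * dt
    if lam <= 0:
        return
    k = rng.poisson(lam)
    if k == 0:
        return
    probs = np.asarray(lengths) / total_len
    which = rng.choice(len(lineages), size=k, p=probs)
    for li in which:
        segs = lineages[li][1]
        seg_len = np.array([e - s for s, e, _ in segs])
        si = rng.choice(len(segs), p=seg_len / seg_len.sum())
        s, e, m = segs[si]
        out.append((rng.uniform(s, e), m))


def simulate_mutations(
    n_samples: int,
    length: float,
    theta_per_base: float,
    rho_per_base: float,
    rng: np.random.Generator,
    group_sizes: tuple[int, int] | None = None,
    split_depth: float = 0.0,
) -> list[tuple[float, int]]:
    """Simulate one chromosome; return [(position, carrier_bitmask), ...].

    ``position`` is a continuous coordinate in [0, length); bit ``i`` of
    the mask is set when sample ``i`` carries the derived allele.  With
    ``group_sizes=(n1, n2)`` samples 0..n1-1 form subpopulation 1 and the
    rest subpopulation 2, separated until ``split_depth``.
    """
    full_mask = (1 << n_samples) - 1
    if group_sizes is None:
        lineages = [(0, [(0.0, float(length), 1 << i)]) for i in range(n_samples)]
        merged = True
    else:
        n1, n2 = group_sizes
        if n1 + n2 != n_samples:
            raise ValueError("group sizes must sum to the sample size")
        lineages = [(0 if i < n1 else 1, [(0.0, float(length), 1 << i)])
                    for i in range(n_samples)]
        merged = split_depth <= 0.0
        if merged:
            lineages = [(0, segs) for _, segs in lineages]

    mutations: list[tuple[float, int]] = []
    t = 0.0
    while lineages:
        if len(lineages) == 1 and rho_per_base == 0:
            break  # single lineage, nothing left to coalesce or mutate onto
        lengths = [_length(segs) for _, segs in lineages]
        total_len = sum(lengths)
        spans = [_span(segs) for _, segs in lineages]
        rec_rate = 0.5 * rho_per_base * sum(spans)
        k_pop = {}
        for pop, _ in lineages:
            k_pop[pop] = k_pop.get(pop, 0) + 1
        coal_rate = sum(k * (k - 1) / 2 for k in k_pop.values())
        total_rate = rec_rate + coal_rate

        if total_rate == 0:
            if not merged:
                _drop_mutations(lineages, lengths, total_len, theta_per_base,
                                split_depth - t, rng, mutations)
                t = split_depth
                lineages = [(0, segs) for _, segs in lineages]
                merged = True
                continue
            break  # isolated lineage without recombination: done

        dt = rng.exponential(1.0 / total_rate)
        if not merged and t + dt > split_depth:
            _drop_mutations(lineages, lengths, total_len, theta_per_base,
                            split_depth - t, rng, mutations)
            t = split_depth
            lineages = [(0, segs) for _, segs in lineages]
            merged = True
            continue

        _drop_mutations(lineages, lengths, total_len, theta_per_base,
                        dt, rng, mutations)
        t += dt

        if rng.uniform() * total_rate < rec_rate:
            # recombination: pick lineage by breakable span, split it
            probs = np.asarray(spans) / sum(spans)
            li = rng.choice(len(lineages), p=probs)
            pop, segs = lineages[li]
            bp = rng.uniform(segs[0][0], segs[-1][1])
            left, right = _split_segments(segs, bp)
            if not left or not right:  # breakpoint at a segment edge
                continue
            lineages[li] = (pop, left)
            lineages.append((pop, right))
        else:
            # coalescence: pick population by pair count, then a pair
            pops = list(k_pop)
            weights = np.array([k_pop[p] * (k_pop[p] - 1) / 2 for p in pops])
            pop = pops[rng.choice(len(pops), p=weights / weights.sum())]
            members = [i for i, (p, _) in enumerate(lineages) if p == pop]
            i, j = rng.choice(len(members), size=2, replace=False)
            a, b = members[i], members[j]
            segs = _merge_segments(lineages[a][1], lineages[b][1], full_mask)
            for idx in sorted((a, b), reverse=True):
                lineages.pop(idx)
            if segs:
                lineages.append((pop, segs))
    mutations.sort(key=lambda mu: mu[0])
    return mutations


def assign_integer_positions(mutations: list[tuple[float, int]],
                             length: int) -> tuple[np.ndarray, np.ndarray]:
    """Snap continuous positions to distinct 0-based integers, keeping order.

    Colliding positions are pushed right to the next free integer (or
    left when the chromosome end is reached), which preserves mutation
    order and the biallelic (one mutation per site) invariant; raises
    :class:`PositionsExhausted` when there are more mutations than
    integer sites.
    """
    if len(mutations) > length:
        raise PositionsExhausted(
            "mutation positions exhausted; increase chromosome length "
            "or lower theta")
    pos = np.empty(len(mutations), dtype=np.int64)
    masks = np.empty(len(mutations), dtype=object)
    prev = -1
    for i, (x, m) in enumerate(mutations):
        pos[i] = max(int(x), prev + 1)
        masks[i] = m
        prev = pos[i]
    # resolve right-edge overflow by shifting earlier sites left
    limit = length
    for i in range(len(mutations) - 1, -1, -1):
        if pos[i] >= limit:
            pos[i] = limit - 1
        limit = pos[i]
    if len(mutations) and pos[0] < 0:
        raise PositionsExhausted(
            "mutation positions exhausted; increase chromosome length "
            "or lower theta")
    return pos, masks
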