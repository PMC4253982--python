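"""Independent brute-force reference implementations used only in tests.

Each oracle recomputes a pipeline quantity by direct enumeration (per-bin
loops, per-bp coverage arrays, threshold scanning) with no shared code
path with the package internals.
"""

from __future__ import annotations

import numpy as np


def brute_max_runs(values, threshold, run_len):
    """Maximal runs of >= run_len consecutive values <= threshold, as
    (first_bin, last_bin) inclusive index pairs, by direct scanning."""
    runs = []
    current = []
    for i, v in enumerate(list(values) + [np.inf]):
        if v <= threshold:
            current.append(i)
        else:
            if len(current) >= run_len:
                runs.append((current[0], current[-1]))
            current = []
    return runs


def brute_replicate_threshold(values_by_chrom, run_len):
    """Smallest candidate threshold (over the sorted distinct values)
    admitting at least one qualifying run on some chromosome."""
    candidates = sorted({float(v) for chrom in values_by_chrom for v in chrom})
    for t in candidates:
        for chrom in values_by_chrom:
            if brute_max_runs(chrom, t, run_len):
                return t
    raise AssertionError("some threshold must admit a run")


def brute_overlap_regions(sweeps_by_population):
    """Per-bp coverage counting on small coordinates.

    Returns {chrom: [(start, end, populations frozenset), ...]} with the
    same touching-atoms-sharing->=2-populations merge rule the package
    documents, recomputed from an explicit per-bp population table.
    """
    by_chrom = {}
    for pop, sweeps in sweeps_by_population.items():
        for sw in sweeps:
            by_chrom.setdefault(sw.chromosome, []).append(sw)
    out = {}
    for chrom, sweeps in by_chrom.items():
        end = max(sw.end for sw in sweeps)
        cover = [set() for _ in range(end)]
        for sw in sweeps:
            for bp in range(sw.start, sw.end):
                cover[bp].add(sw.population)
        regions = []
        current = None  # [start, end, set]
        for bp in range(end + 1):
            pops = cover[bp] if bp < end else set()
            if len(pops) >= 2:
                if (
                    current is not None
                    and current[1] == bp
                    and len(current[2] & pops) >= 2
                ):
                    current[1] = bp + 1
                    current[2] |= pops
                else:
                    if current is not None:
                        regions.append(current)
                    current = [bp, bp + 1, set(pops)]
            else:
                if current is not None:
                    regions.append(current)
                    current = None
        out[chrom] = [(s, e, frozenset(p)) for s, e, p in regions]
    return out
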