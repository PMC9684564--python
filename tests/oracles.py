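"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written directly from first principles (raw intensities,
exhaustive enumeration, exact rational arithmetic, textbook formulas) and
shares no code path with the package.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction
from typing import Iterable, Mapping

from baitcall.io import ProteinGroupTable, Pulldown, SampleDesign


def brute_force_candidates(
    table: ProteinGroupTable,
    design: SampleDesign,
    q_max: float = 0.01,
    min_reps: int | str = "all",
    control_any: bool = True,
) -> dict[str, set[str]]:
    """Direct per-(protein, condition) evaluation from raw intensities."""
    out: dict[str, set[str]] = {}
    for condition in design.conditions:
        baits = [
            s
            for s, e in design.entries.items()
            if e.condition == condition and e.pulldown is Pulldown.BAIT
        ]
        controls = [
            s
            for s, e in design.entries.items()
            if e.condition == condition and e.pulldown is Pulldown.CONTROL
        ]
        called: set[str] = set()
        for rec in table.records:
            if rec.q_value >= q_max or rec.is_reverse or rec.is_contaminant:
                continue
            n_detected = sum(1 for s in baits if rec.intensity(s) > 0)
            need = len(baits) if min_reps == "all" else int(min_reps)
            if n_detected < need:
                continue
            ctrl_hits = [rec.intensity(s) > 0 for s in controls]
            in_controls = any(ctrl_hits) if control_any else (
                all(ctrl_hits) and bool(ctrl_hits)
            )
            if not in_controls:
                called.add(rec.group_id)
        out[condition] = called
    return out


def brute_force_regions(
    sets: Mapping[str, Iterable[str]],
) -> dict[frozenset[str], int]:
    """Region counts by checking every identifier against every signature."""
    sets = {k: set(v) for k, v in sets.items()}
    labels = list(sets)
    counts: dict[frozenset[str], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            signature = frozenset(combo)
            n = 0
            for identifier in set().union(*sets.values()):
                member_of = frozenset(l for l in labels if identifier in sets[l])
                if member_of == signature:
                    n += 1
            counts[signature] = n
    return counts


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> Fraction:
    """Exact-rational P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(n, K) + 1):
        if n - i > N - K:
            continue
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return Fraction(acc, total)


def pearson_direct(x: list[float], y: list[float]) -> float:
    """Textbook covariance-formula Pearson over paired values."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)
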