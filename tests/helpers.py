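"""Independent reference implementations used as test oracles.

These deliberately re-derive results by the most direct route available
(naive chronological scan, closed-form normal equations) and never call the
code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def brute_force_collapse(records, window_minutes):
    """Naive O(n^2) chronological event scan.

    Walks records in time order per structure; each record joins the
    most-recently opened event with the same species and individual count
    when it falls within ``window_minutes`` of that event's first record,
    otherwise it opens a new event.
    """
    events = []  # dicts: structure_id, species, count, start, n
    ordered = sorted(records, key=lambda r: (r.structure_id, r.timestamp, r.camera_id))
    for rec in ordered:
        candidates = [
            e
            for e in events
            if e["structure_id"] == rec.structure_id
            and e["species"] == rec.species
            and e["count"] == rec.count
        ]
        target = max(candidates, key=lambda e: e["start"], default=None)
        if (
            target is not None
            and window_minutes > 0
            and (rec.timestamp - target["start"]).total_seconds()
            <= window_minutes * 60.0
        ):
            target["n"] += 1
        else:
            events.append(
                {
                    "structure_id": rec.structure_id,
                    "species": rec.species,
                    "count": rec.count,
                    "start": rec.timestamp,
                    "n": 1,
                }
            )
    events.sort(key=lambda e: (e["structure_id"], e["start"], e["species"], e["count"]))
    return [
        (e["structure_id"], e["species"], e["start"], e["count"], e["n"])
        for e in events
    ]


def closed_form_ols(x, y):
    """Two-parameter least squares by the normal equations.

    Returns (slope, intercept, r2, adjusted_r2, t, p_two_sided).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    sse = float((resid**2).sum())
    sst = float(((y - ym) ** 2).sum())
    r2 = 1.0 - sse / sst
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    se_slope = math.sqrt(sse / (n - 2) / sxx)
    t = slope / se_slope
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return slope, intercept, r2, adj, t, p
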