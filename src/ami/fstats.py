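"""Outgroup f3 statistics.

f3(O; A, B) = mean over sites of (f_O − f_A)(f_O − f_B): the shared
drift of A and B relative to an outgroup O.  Larger values mean A and B
share more post-outgroup history; here it validates estimated ancestral
frequencies against actual individual genomes.  Point estimates only —
no block jackknife or small-sample bias correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class F3Result:
    pop_a: str
    pop_b: str
    outgroup: str
    f3: float
    n_sites: int


def outgroup_f3(
    f_a: np.ndarray,
    f_b: np.ndarray,
    f_o: np.ndarray,
    names: tuple[str, str, str] = ("A", "B", "O"),
) -> F3Result:
    """Mean of (f_O − f_A)(f_O − f_B) over sites with all three defined."""
    f_a = np.asarray(f_a, dtype=float)
    f_b = np.asarray(f_b, dtype=float)
    f_o = np.asarray(f_o, dtype=float)
    if not (len(f_a) == len(f_b) == len(f_o)):
        raise ValueError("frequency vectors must align")
    ok = np.isfinite(f_a) & np.isfinite(f_b) & np.isfinite(f_o)
    if not ok.any():
        raise ValueError("no sites with all three frequencies defined")
    val = float(((f_o[ok] - f_a[ok]) * (f_o[ok] - f_b[ok])).mean())
    return F3Result(pop_a=names[0], pop_b=names[1], outgroup=names[2],
                    f3=val, n_sites=int(ok.sum()))


def pairwise_f3_matrix(
    freqs: pd.DataFrame, populations: list[str], outgroup: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric matrix of outgroup f3 over population frequency columns.

    ``freqs`` holds one frequency column per population (NaN = missing
    at that site for that population).  Returns (f3 matrix, per-pair
    site-count matrix).
    """
    if len(populations) < 2:
        raise ValueError("need at least two populations besides the outgroup")
    if outgroup not in freqs.columns:
        raise KeyError(f"outgroup column {outgroup!r} missing")
    f_o = freqs[outgroup].to_numpy(dtype=float)
    vals = pd.DataFrame(index=populations, columns=populations, dtype=float)
    counts = pd.DataFrame(index=populations, columns=populations, dtype="Int64")
    for i, a in enumerate(populations):
        for b in populations[i:]:
            res = outgroup_f3(freqs[a].to_numpy(dtype=float),
                              freqs[b].to_numpy(dtype=float),
                              f_o, names=(a, b, outgroup))
            vals.loc[a, b] = vals.loc[b, a] = res.f3
            counts.loc[a, b] = counts.loc[b, a] = res.n_sites
    return vals, counts
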