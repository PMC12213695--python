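"""Metabolite-table normalization.

Concentrations quantified against an internal standard in one acquisition
are put on a common scale by probabilistic quotient normalization (PQN):
each sample is divided by the median of its metabolite-wise quotients
against a reference sample, which is robust to a minority of genuinely
changed metabolites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PQNResult:
    """PQN output: normalized table, per-sample dilution factors, flagged samples."""

    data: pd.DataFrame
    factors: pd.Series
    flagged: list = field(default_factory=list)


def pqn_normalize(
    table: pd.DataFrame,
    reference_id=None,
    min_shared_fraction: float = 0.5,
) -> PQNResult:
    """Probabilistic quotient normalization against one reference sample.

    For each sample the quotients ``q_j = x_j / ref_j`` are formed over
    metabolites positive in both the sample and the reference, and the
    sample is divided by ``median(q)``.  The reference row is returned
    unchanged (its median quotient is exactly 1).

    Parameters
    ----------
    table
        Samples x metabolites non-negative concentration matrix.
    reference_id
        Row to normalize against; defaults to the first row (mirroring
        quantification in the first acquired sample).
    min_shared_fraction
        Minimum fraction of metabolites that must be positive in the
        reference row.

    Samples sharing fewer than two positive metabolites with the
    reference are left unnormalized (factor NaN), listed in ``flagged``
    and warned about rather than silently rescaled.
    """
    arr = table.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative concentrations")
    if reference_id is None:
        reference_id = table.index[0]
    if reference_id not in table.index:
        raise ValueError(f"reference sample {reference_id!r} not in table")
    ref = table.loc[reference_id].to_numpy(dtype=float)
    ref_pos = ref > 0
    if ref_pos.mean() < min_shared_fraction:
        raise ValueError(
            f"reference {reference_id!r} is positive on {ref_pos.mean():.0%} of "
            f"metabolites, below the required {min_shared_fraction:.0%}"
        )

    factors = pd.Series(np.nan, index=table.index, name="pqn_factor", dtype=float)
    out = table.to_numpy(dtype=float).copy()
    flagged = []
    for i, sid in enumerate(table.index):
        if sid == reference_id:
            factors[sid] = 1.0
            continue
        shared = ref_pos & (out[i] > 0)
        if shared.sum() < 2:
            flagged.append(sid)
            continue
        factor = float(np.median(out[i, shared] / ref[shared]))
        factors[sid] = factor
        out[i] = out[i] / factor
    if flagged:
        warnings.warn(
            f"{len(flagged)} sample(s) share < 2 positive metabolites with the "
            f"reference and were left unnormalized: {list(map(str, flagged))}",
            UserWarning,
            stacklevel=2,
        )
    return PQNResult(
        data=pd.DataFrame(out, index=table.index, columns=table.columns),
        factors=factors,
        flagged=flagged,
    )
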