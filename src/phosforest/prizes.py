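"""Per-protein prizes from site-level phosphoproteomic measurements.

Each phosphosite row holds per-channel (per-sample) intensities.  Intensities
are normalized to the row mean to give per-sample fold changes; the prize of a
protein in a sample is the maximum over its sites of |log fold change|.  A
protein with prize zero carries no evidence and is excluded from the terminal
set.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Prize assigned to a site whose fold change is exactly 0 in a sample
#: (the channel is empty while others are not; |log 0| is infinite).
DEFAULT_PRIZE_CAP = 10.0


class PhosphoError(ValueError):
    """Raised on malformed phosphoproteomic input."""


def read_phospho_table(path) -> pd.DataFrame:
    """Read a TSV with header ``protein  site  <sample columns...>``.

    Returns a DataFrame indexed by (protein, site) with one column per sample.
    """
    df = pd.read_csv(Path(path), sep="\t")
    if df.shape[1] < 3:
        raise PhosphoError("phospho table needs protein, site and >=1 sample column")
    df = df.rename(columns={df.columns[0]: "protein", df.columns[1]: "site"})
    if df.duplicated(["protein", "site"]).any():
        raise PhosphoError("duplicate (protein, site) rows in phospho table")
    out = df.set_index(["protein", "site"])
    if (out.values < 0).any():
        raise PhosphoError("negative intensities in phospho table")
    if (out.sum(axis=1) <= 0).any():
        raise PhosphoError("phospho table contains an all-zero site row")
    return out


def channel_fold_changes(intensities) -> np.ndarray:
    """Fold change per channel: intensity divided by the mean of all channels."""
    arr = np.asarray(intensities, dtype=float)
    mean = arr.mean()
    if mean <= 0:
        raise PhosphoError("cannot normalize an all-zero intensity row")
    return arr / mean


def prizes_from_phospho(
    table: pd.DataFrame,
    sample,
    log_base: float = 2.0,
    prize_cap: float = DEFAULT_PRIZE_CAP,
) -> Dict[str, float]:
    """Per-protein prizes for one sample: max over sites of |log fold change|.

    ``sample`` may be a column label or integer position.  Fold changes are
    computed per site against the mean of all channels.  A fold change of 0
    (site unobserved in this channel) contributes the cap value; a protein
    whose every site has fold change 0 is treated as unobserved and excluded.
    Proteins with prize exactly 0 are excluded from the terminal set.
    """
    if log_base <= 1:
        raise PhosphoError(f"log base must exceed 1, got {log_base}")
    if table.empty:
        logger.warning("empty phospho table: empty prize map")
        return {}
    if sample in table.columns:
        col = sample
    elif isinstance(sample, int) and 0 <= sample < table.shape[1]:
        col = table.columns[sample]
    else:
        raise PhosphoError(f"unknown sample {sample!r}")

    log_denom = math.log(log_base)
    prizes: Dict[str, float] = {}
    observed: Dict[str, bool] = {}
    n_capped = 0
    for (protein, _site), row in table.iterrows():
        fc = channel_fold_changes(row.values)[table.columns.get_loc(col)]
        if fc == 0.0:
            site_prize = prize_cap
            n_capped += 1
            seen = False
        else:
            site_prize = min(abs(math.log(fc) / log_denom), prize_cap)
            seen = True
        observed[protein] = observed.get(protein, False) or seen
        prizes[protein] = max(prizes.get(protein, 0.0), site_prize)
    if n_capped:
        logger.warning("%d site(s) had fold change 0; prize capped at %g",
                       n_capped, prize_cap)
    return {
        p: v
        for p, v in prizes.items()
        if v > 0.0 and observed[p]
    }


def write_prizes(prizes: Dict[str, float], path) -> None:
    """Write a 2-column TSV (protein, prize), sorted by protein."""
    with open(Path(path), "w") as fh:
        fh.write("protein\tprize\n")
        for protein in sorted(prizes):
            fh.write(f"{protein}\t{prizes[protein]:.10g}\n")


def read_prizes(path) -> Dict[str, float]:
    """Read a 2-column prize TSV (with or without header)."""
    prizes: Dict[str, float] = {}
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and parts[-1] == "prize":
                continue
            try:
                value = float(parts[1])
            except (IndexError, ValueError) as exc:
                raise PhosphoError(f"{path}:{lineno}: malformed prize row") from exc
            if value < 0:
                raise PhosphoError(f"{path}:{lineno}: negative prize {value}")
            if value > 0:
                prizes[parts[0]] = value
    return prizes
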