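"""MS1 quantification of glutamylation-state distributions.

Intensities are read per glutamylation state k (number of added Glu units)
from an integrated MS1 peak table, corrected for the fraction of the isotope
envelope actually summed, and normalized with the before/after *pool rule*:
the combined normalized intensity of the peptide pool before and after the
enzyme reaction equals 1, so state fractions are directly comparable across
the two conditions.  Ionization efficiency is assumed equal across k — the
standard (and here explicit) caveat of label-free state quantification.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .mass import composition, envelope, mz as adduct_mz
from .tails import Peptidoform

__all__ = [
    "extract_state_intensities",
    "normalize_pool",
    "conversion_fraction",
    "state_distribution",
    "quant_summary",
]

QUANT_COLUMNS = ["variant", "k", "condition", "raw_intensity"]

_env_cache: dict[tuple, list[tuple[float, float]]] = {}


def _cached_envelope(p: Peptidoform, prune: float) -> list[tuple[float, float]]:
    key = (composition(p).frozen(), prune)
    if key not in _env_cache:
        _env_cache[key] = envelope(composition(p), prune=prune)
    return _env_cache[key]


def extract_state_intensities(
    ms1: pd.DataFrame,
    series: Sequence[Peptidoform],
    tol_ppm: float = 10.0,
    charges: Sequence[int] = (2, 3),
    top_n: int = 3,
    variant: str = "",
    condition: str = "after",
    prune: float = 1e-4,
) -> pd.DataFrame:
    """Per-state raw intensities from an integrated MS1 peak table.

    ``ms1`` needs columns ``mz`` and ``intensity`` (a simulator MS1 table or
    a vendor-exported XIC/peak export).  For each peptidoform (the series
    members must differ only in total added Glu k) the ``top_n`` most
    abundant theoretical isotopologues are looked up at every charge state;
    each observed row is apportioned to the nearest theoretical target within
    ``tol_ppm``.  The matched sum is divided by the theoretical abundance
    fraction of the matched isotopologues, so states of different envelope
    width are comparable.  Overlapping targets from different states trigger
    a warning and are resolved by the nearest-theoretical rule.
    """
    if ms1.empty or not len(series):
        return pd.DataFrame(columns=QUANT_COLUMNS)
    ks = [p.total_added_glu for p in series]
    if len(set(ks)) != len(ks):
        raise ValueError("series members must have distinct added-Glu counts")
    # targets: (target_mz, form_index, charge_index, abundance_fraction)
    targets: list[tuple[float, int, int, float]] = []
    for fi, p in enumerate(series):
        env = _cached_envelope(p, prune)
        top = sorted(env, key=lambda t: -t[1])[:top_n]
        for zi, z in enumerate(charges):
            for m, a in top:
                targets.append((adduct_mz(m, z, "protonated"), fi, zi, a))
    targets.sort()
    tmz = np.array([t[0] for t in targets])
    # warn on targets of different states closer than the matching tolerance
    for a, b in zip(targets, targets[1:]):
        if a[1] != b[1] and (b[0] - a[0]) / a[0] * 1e6 < tol_ppm:
            warnings.warn(
                f"state envelopes overlap within {tol_ppm} ppm near m/z {a[0]:.4f}; "
                "intensities apportioned to the nearest theoretical peak",
                stacklevel=2,
            )
            break
    obs_mz = ms1["mz"].to_numpy(dtype=float)
    obs_int = ms1["intensity"].to_numpy(dtype=float)
    idx = np.searchsorted(tmz, obs_mz)
    # per (form, charge): matched intensity and the envelope fraction of the
    # isotopologues that actually matched, so a dropped peak does not bias
    # the state downward
    matched = np.zeros((len(series), len(charges)))
    matched_fraction = np.zeros((len(series), len(charges)))
    hit: set[int] = set()
    for row, (m, inten) in enumerate(zip(obs_mz, obs_int)):
        best = None
        for j in (idx[row] - 1, idx[row]):
            if 0 <= j < len(targets):
                ppm = abs(m - tmz[j]) / tmz[j] * 1e6
                if ppm <= tol_ppm and (best is None or ppm < best[0]):
                    best = (ppm, j)
        if best is None:
            continue
        j = best[1]
        _, fi, zi, a = targets[j]
        matched[fi, zi] += inten
        if j not in hit:
            hit.add(j)
            matched_fraction[fi, zi] += a
    with np.errstate(invalid="ignore", divide="ignore"):
        per_charge = np.where(matched_fraction > 0, matched / matched_fraction, 0.0)
    raw = per_charge.sum(axis=1)
    return pd.DataFrame(
        {
            "variant": variant,
            "k": ks,
            "condition": condition,
            "raw_intensity": raw,
        }
    ).sort_values("k", ignore_index=True)


def normalize_pool(before: pd.DataFrame, after: pd.DataFrame) -> pd.DataFrame:
    """Pool normalization: every raw intensity divided by the grand total of
    the combined before+after tables, so the whole pool sums to exactly 1."""
    if set(before["variant"]) != set(after["variant"]):
        raise ValueError("before/after tables must share variant keys")
    pool = pd.concat([before, after], ignore_index=True)
    total = float(pool["raw_intensity"].sum())
    if total <= 0:
        raise ValueError("zero grand total; nothing to normalize")
    pool = pool.copy()
    pool["normalized_intensity"] = pool["raw_intensity"] / total
    return pool


def conversion_fraction(table: pd.DataFrame) -> pd.Series:
    """Fraction of each variant's after-condition intensity carrying k >= 1
    added glutamates (the fraction of substrate converted by the enzyme)."""
    col = "normalized_intensity" if "normalized_intensity" in table else "raw_intensity"
    after = table[table["condition"] == "after"]
    out = {}
    for variant, grp in after.groupby("variant"):
        tot = grp[col].sum()
        out[variant] = float(grp.loc[grp["k"] >= 1, col].sum() / tot) if tot > 0 else 0.0
    return pd.Series(out, name="conversion_fraction")


def state_distribution(table: pd.DataFrame, condition: str = "after") -> pd.Series:
    """Normalized distribution over glutamylation states k for one condition
    (sums to 1 over k within the condition)."""
    col = "normalized_intensity" if "normalized_intensity" in table else "raw_intensity"
    sub = table[table["condition"] == condition]
    dist = sub.groupby("k")[col].sum()
    total = dist.sum()
    if total <= 0:
        raise ValueError(f"no intensity in condition {condition!r}")
    return dist / total


def quant_summary(table: pd.DataFrame) -> dict:
    """JSON-ready summary: per-variant conversion and chain-length histogram."""
    conv = conversion_fraction(table)
    out: dict = {"variants": {}}
    for variant in conv.index:
        sub = table[table["variant"] == variant]
        hist = state_distribution(sub, "after")
        out["variants"][variant] = {
            "conversion_fraction": round(float(conv[variant]), 6),
            "state_distribution_after": {int(k): round(float(v), 6) for k, v in hist.items()},
        }
    out["caveat"] = (
        "equal ionization efficiency assumed across glutamylation states; "
        "isobaric branched/extended forms are quantified jointly at MS1 "
        "unless localization results split them"
    )
    return out
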