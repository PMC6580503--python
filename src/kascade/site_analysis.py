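"""Descriptive statistics contrasting acetylated and non-acetylated lysines.

All outputs are tidy pandas DataFrames ready for TSV export: per-position
physicochemical property profiles (mean +/- standard error), per-position
Shannon information entropy, per-position/per-residue composition bias with a
two-proportion z-test, secondary-structure state frequencies at the site
(F_i = N_i / N over the seven DSSP states, coil taking the remainder), and
binned ASA distributions.  Window positions are reported relative to the
centre lysine (position 0); padding 'X' is excluded from every frequency
denominator.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy as shannon_entropy
from statsmodels.stats.proportion import proportions_ztest

from .feature_encoding import SS_STATES, NormalizedProperty, StructureAnnotation
from .sequence_io import STANDARD_AA, PeptideWindow, SiteRecord

_CLASS_NAME = {1: "positive", 0: "negative"}


def _split_by_label(windows: Sequence[PeptideWindow]) -> dict[int, list[PeptideWindow]]:
    out: dict[int, list[PeptideWindow]] = {1: [], 0: []}
    for w in windows:
        if w.label is None:
            raise ValueError(f"window {w.protein_id}:{w.center_position} has no label")
        out[w.label].append(w)
    return out


def property_profile(
    windows: Sequence[PeptideWindow], prop: NormalizedProperty
) -> pd.DataFrame:
    """Per-position mean and standard error of a standardised property, by class.

    'X' positions are excluded from the averages; SE is the sample SD divided
    by sqrt(n) (0 when n <= 1).  Columns: class, rel_pos, mean, se, n.
    """
    by_label = _split_by_label(windows)
    flank = windows[0].flank
    rows = []
    for label, group in by_label.items():
        for r in range(-flank, flank + 1):
            vals = [
                prop.z(w.residues[flank + r])
                for w in group
                if w.residues[flank + r] != "X"
            ]
            n = len(vals)
            mean = float(np.mean(vals)) if n else np.nan
            se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            rows.append(
                {"class": _CLASS_NAME[label], "rel_pos": r, "mean": mean, "se": se, "n": n}
            )
    return pd.DataFrame(rows)


def entropy_profile(windows: Sequence[PeptideWindow]) -> pd.DataFrame:
    """Per-position Shannon entropy (bits) of amino-acid usage, by class.

    IE(pos) = -sum_a f_a log2 f_a over the 20 amino-acid frequencies at that
    position, 'X' excluded from the denominator.  Low entropy means a
    conserved position.  Columns: class, rel_pos, entropy, n.
    """
    by_label = _split_by_label(windows)
    flank = windows[0].flank
    rows = []
    for label, group in by_label.items():
        for r in range(-flank, flank + 1):
            letters = [w.residues[flank + r] for w in group if w.residues[flank + r] != "X"]
            n = len(letters)
            if n == 0:
                ie = np.nan
            else:
                counts = Counter(letters)
                freqs = np.array([counts.get(a, 0) for a in STANDARD_AA], dtype=float) / n
                ie = float(shannon_entropy(freqs, base=2))
            rows.append(
                {"class": _CLASS_NAME[label], "rel_pos": r, "entropy": ie, "n": n}
            )
    return pd.DataFrame(rows)


def composition_bias(
    pos_windows: Sequence[PeptideWindow],
    neg_windows: Sequence[PeptideWindow],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-position, per-residue frequency difference with a two-proportion z-test.

    For every window position and amino acid the positive-class frequency is
    compared against the negative-class frequency (pooled two-sided z-test);
    residues with p < alpha are called 'enriched' or 'depleted' in the
    positive class.  This is the numerical core of a two-sample logo; no
    graphics are produced.  Columns: rel_pos, residue, freq_pos, freq_neg,
    diff, p_value, significant, direction.
    """
    if not pos_windows or not neg_windows:
        raise ValueError("both classes must be non-empty")
    flank = pos_windows[0].flank
    rows = []
    for r in range(-flank, flank + 1):
        pos_letters = [w.residues[flank + r] for w in pos_windows if w.residues[flank + r] != "X"]
        neg_letters = [w.residues[flank + r] for w in neg_windows if w.residues[flank + r] != "X"]
        n1, n0 = len(pos_letters), len(neg_letters)
        c1, c0 = Counter(pos_letters), Counter(neg_letters)
        for aa in STANDARD_AA:
            k1, k0 = c1.get(aa, 0), c0.get(aa, 0)
            f1 = k1 / n1 if n1 else np.nan
            f0 = k0 / n0 if n0 else np.nan
            pooled = (k1 + k0) / (n1 + n0) if (n1 + n0) else np.nan
            if n1 == 0 or n0 == 0 or pooled in (0.0, 1.0):
                p = 1.0  # no evidence either way
            else:
                _, p = proportions_ztest([k1, k0], [n1, n0], alternative="two-sided")
                p = float(p)
            diff = f1 - f0
            sig = bool(p < alpha) and diff != 0
            rows.append(
                {
                    "rel_pos": r,
                    "residue": aa,
                    "freq_pos": f1,
                    "freq_neg": f0,
                    "diff": diff,
                    "p_value": p,
                    "significant": sig,
                    "direction": ("enriched" if diff > 0 else "depleted") if sig else "none",
                }
            )
    return pd.DataFrame(rows)


def _center_letters(
    sites: Sequence[SiteRecord], annotations: Mapping[str, StructureAnnotation]
) -> dict[int, list[str]]:
    out: dict[int, list[str]] = {1: [], 0: []}
    for s in sites:
        ann = annotations.get(s.protein_id)
        if ann is None:
            raise KeyError(f"no structure annotation for protein {s.protein_id!r}")
        out[s.label].append(ann.ss[s.position - 1])
    return out


def ss_frequency(
    sites: Sequence[SiteRecord], annotations: Mapping[str, StructureAnnotation]
) -> pd.DataFrame:
    """Secondary-structure state frequencies at the site residue, by class.

    F_i = N_i / N for i in {H, B, E, G, I, T, S}; the coil remainder is
    reported as state '-'.  Columns: class, state, count, frequency.
    """
    letters = _center_letters(sites, annotations)
    rows = []
    for label, group in letters.items():
        n = len(group)
        if n == 0:
            raise ValueError(f"no sites in class {_CLASS_NAME[label]}")
        counts = Counter(group)
        for state in SS_STATES + "-":
            k = counts.get(state, 0)
            rows.append(
                {
                    "class": _CLASS_NAME[label],
                    "state": state,
                    "count": k,
                    "frequency": k / n,
                }
            )
    return pd.DataFrame(rows)


def asa_distribution(
    sites: Sequence[SiteRecord],
    annotations: Mapping[str, StructureAnnotation],
    bin_width: float = 10.0,
    upper: float = 150.0,
) -> pd.DataFrame:
    """Normalised histogram of site-residue ASA values per class.

    Bins of ``bin_width`` square angstroms from 0 up to ``upper``; the final
    bin is open-ended (``[upper, inf)``).  Columns: class, bin_low, bin_high,
    count, frequency.
    """
    edges = list(np.arange(0.0, upper + bin_width / 2, bin_width)) + [np.inf]
    rows = []
    values: dict[int, list[float]] = {1: [], 0: []}
    for s in sites:
        ann = annotations.get(s.protein_id)
        if ann is None:
            raise KeyError(f"no structure annotation for protein {s.protein_id!r}")
        values[s.label].append(float(ann.asa[s.position - 1]))
    for label, vals in values.items():
        n = len(vals)
        if n == 0:
            raise ValueError(f"no sites in class {_CLASS_NAME[label]}")
        counts, _ = np.histogram(vals, bins=edges)
        for lo, hi, k in zip(edges[:-1], edges[1:], counts):
            rows.append(
                {
                    "class": _CLASS_NAME[label],
                    "bin_low": lo,
                    "bin_high": hi,
                    "count": int(k),
                    "frequency": int(k) / n,
                }
            )
    return pd.DataFrame(rows)
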