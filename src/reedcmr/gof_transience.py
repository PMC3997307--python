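"""Directional goodness-of-fit test for transience (the 3.SR component).

For each occasion i the individuals captured at i are cross-classified as
newly versus previously marked, and as reencountered at some later occasion
versus never seen again.  Transients — birds passing through with no chance
of staying — depress the reencounter rate of the newly marked row.  Each
2x2 table yields a signed square-root of the Pearson chi-square statistic
(positive when newly marked birds are reencountered less than expected);
the components are combined as Z = sum(z_i) / sqrt(M) over the M
informative tables, referred to the standard normal for a one-sided test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .preprocess import EncounterHistoryMatrix


@dataclass
class TransienceTable:
    """2x2 cross-classification at one occasion.

    Rows: newly marked at i, previously marked at i.
    Columns: reencountered at any occasion > i, never reencountered.
    """

    occasion: int
    counts: np.ndarray  # (2, 2) int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2) or (self.counts < 0).any():
            raise ValueError("counts must be a nonnegative 2x2 table")

    @property
    def informative(self) -> bool:
        """True when both row and both column margins are positive."""
        return bool(
            (self.counts.sum(axis=1) > 0).all() and (self.counts.sum(axis=0) > 0).all()
        )

    def chi2_and_z(self) -> tuple[float, float]:
        """Pearson chi-square (no continuity correction) and the signed root.

        The sign is positive when the newly marked row is reencountered
        less than expected under independence (the transience direction).
        """
        (a, b), (c, d) = self.counts
        n = a + b + c + d
        r1, r2 = a + b, c + d
        c1, c2 = a + c, b + d
        denom = r1 * r2 * c1 * c2
        if denom == 0:
            return np.nan, np.nan
        delta = a * d - b * c
        chi2 = n * delta**2 / denom
        sign = 1.0 if delta < 0 else (-1.0 if delta > 0 else 0.0)
        return float(chi2), float(sign * np.sqrt(chi2))


@dataclass
class GOFResult:
    tables: list[TransienceTable]
    z_components: np.ndarray  # per informative table
    chi2_components: np.ndarray
    statistic: float  # pooled directional Z
    p_value: float  # one-sided, large Z => transience
    n_informative: int
    status: str = "ok"  # "no-informative-tables" when M = 0


def transience_tables(histories: EncounterHistoryMatrix) -> list[TransienceTable]:
    """Build the per-occasion 2x2 tables for occasions 1..T-1.

    Only individuals detected at occasion i contribute to table i.  The
    final occasion has no "seen later" column and produces no table.
    """
    det = histories.detections
    first = histories.first_capture
    n, T = det.shape
    tables = []
    for i in range(T - 1):
        at_i = det[:, i] == 1
        if not at_i.any():
            tables.append(TransienceTable(i, np.zeros((2, 2), dtype=np.int64)))
            continue
        new = first == i
        seen_later = det[:, i + 1 :].any(axis=1)
        a = int((at_i & new & seen_later).sum())
        b = int((at_i & new & ~seen_later).sum())
        c = int((at_i & ~new & seen_later).sum())
        d = int((at_i & ~new & ~seen_later).sum())
        tables.append(TransienceTable(i, np.array([[a, b], [c, d]])))
    return tables


def test_3sr(tables: list[TransienceTable]) -> GOFResult:
    """Pooled directional z-test for transience over the informative tables."""
    informative = [t for t in tables if t.informative]
    M = len(informative)
    if M == 0:
        return GOFResult(
            tables=tables,
            z_components=np.array([]),
            chi2_components=np.array([]),
            statistic=np.nan,
            p_value=np.nan,
            n_informative=0,
            status="no-informative-tables",
        )
    chi2 = np.empty(M)
    z = np.empty(M)
    for k, t in enumerate(informative):
        chi2[k], z[k] = t.chi2_and_z()
    Z = z.sum() / np.sqrt(M)
    p = float(norm.sf(Z))
    return GOFResult(
        tables=tables,
        z_components=z,
        chi2_components=chi2,
        statistic=float(Z),
        p_value=p,
        n_informative=M,
    )


def gof_report(result: GOFResult) -> str:
    """Human-readable structured-text report of the 3.SR test."""
    lines = ["Directional z-test for transience (3.SR)", "=" * 42]
    k = 0
    for t in result.tables:
        (a, b), (c, d) = t.counts
        line = (
            f"occasion {t.occasion + 1}: new [{a} seen-again, {b} not] "
            f"old [{c} seen-again, {d} not]"
        )
        if t.informative:
            line += f"  chi2={result.chi2_components[k]:.4f} z={result.z_components[k]:+.4f}"
            k += 1
        else:
            line += "  (uninformative: zero margin)"
        lines.append(line)
    lines.append("-" * 42)
    lines.append(f"informative tables M = {result.n_informative}")
    if result.status == "ok":
        lines.append(f"Z = {result.statistic:.4f}")
        lines.append(f"one-sided P = {result.p_value:.6g}")
    else:
        lines.append("Z undefined: no informative tables")
    return "\n".join(lines)
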