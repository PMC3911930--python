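"""Aggregation of per-subject complexity rankings and correlation reports.

Each participant clusters the images into three groups — simple,
ordinary, complex — and orders the images within each group by
increasing complexity.  The two group boundaries are themselves
rankable items ("division markers"), so a session with n images yields
a sequence of n + 2 rank positions (76 positions for 74 images).

Across participants the rank position of an item is a random variable;
its distribution is summarized by per-position counts, the probability
mass p(r), and the mean rank mu = sum_r r * p(r).  Items (and the two
divisions) sorted by mu form the aggregate subjective rank, and the
division means induce the final simple/ordinary/complex partition.

Objective measures are compared against mu by Pearson correlation with
a two-sided t-test p-value and a first-order least-squares fit,
optionally on subsets (dayscapes, nightscapes, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Internal identifiers for the two group-division markers.
DIV_SIMPLE_ORDINARY = "<division:simple|ordinary>"
DIV_ORDINARY_COMPLEX = "<division:ordinary|complex>"
DIVISIONS = (DIV_SIMPLE_ORDINARY, DIV_ORDINARY_COMPLEX)

#: Token used for either division in the CSV rank-file dialect.
DIVISION_TOKEN = "|"

#: Significance criterion for bolding correlations in reports.
DEFAULT_ALPHA = 0.001


@dataclass
class SubjectRanking:
    """One participant's grouped ordering of all items."""

    subject_id: str
    simple: list = field(default_factory=list)
    ordinary: list = field(default_factory=list)
    complex: list = field(default_factory=list)

    @property
    def items(self) -> list:
        return list(self.simple) + list(self.ordinary) + list(self.complex)

    def sequence(self) -> list:
        """Full rank sequence including the two division markers."""
        return insert_divisions(self.simple, self.ordinary, self.complex)


@dataclass
class RankDistribution:
    """Distribution of one item's rank position across participants."""

    item: str
    counts: np.ndarray        # counts per position r = 1..R
    n_subjects: int

    @property
    def p(self) -> np.ndarray:
        return self.counts / self.n_subjects

    @property
    def mu(self) -> float:
        r = np.arange(1, self.counts.size + 1)
        return float((r * self.p).sum())

    @property
    def sigma(self) -> float:
        r = np.arange(1, self.counts.size + 1)
        return float(np.sqrt(((r - self.mu) ** 2 * self.p).sum()))


@dataclass
class CorrelationReport:
    """Pearson correlation of one objective measure with the mean rank."""

    measure: str
    r: float
    p_value: float
    slope: float
    intercept: float
    n: int
    subset: str = "all"
    alpha: float = DEFAULT_ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def insert_divisions(simple, ordinary, complex) -> list:
    """Build the full rank sequence with the two division markers.

    Positions run 1..|simple|, then the simple/ordinary division, then
    the ordinary items, then the ordinary/complex division, then the
    complex items — so if the simple group holds ten items, the first
    division occupies position 11.
    """
    groups = (list(simple), list(ordinary), list(complex))
    seq = groups[0] + [DIV_SIMPLE_ORDINARY] + groups[1] \
        + [DIV_ORDINARY_COMPLEX] + groups[2]
    seen = set()
    for item in seq:
        if item in seen:
            raise ValueError(f"item {item!r} appears more than once")
        seen.add(item)
    return seq


def rank_distribution(sequences: dict, item: str) -> RankDistribution:
    """Count how often ``item`` lands at each rank position.

    ``sequences`` maps subject id -> full rank sequence (all sequences
    must have equal length R).  Positions are 1-based.
    """
    if not sequences:
        raise ValueError("need at least one subject")
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError(f"subjects disagree on sequence length: {sorted(lengths)}")
    r_max = lengths.pop()
    counts = np.zeros(r_max, dtype=int)
    for subject, seq in sequences.items():
        try:
            pos = seq.index(item)
        except ValueError:
            raise ValueError(
                f"item {item!r} missing from subject {subject!r}") from None
        counts[pos] += 1
    return RankDistribution(item=item, counts=counts,
                            n_subjects=len(sequences))


def rank_distributions(sequences: dict) -> dict:
    """Distributions for every item (divisions included)."""
    first = next(iter(sequences.values()))
    return {item: rank_distribution(sequences, item) for item in first}


def aggregate_rank(distributions: dict) -> pd.DataFrame:
    """Sort items by mean rank and classify them by the division means.

    Returns a DataFrame (item, mu, sigma, group) in ascending mu order;
    mu ties break by item identifier.  Items with mu below the
    simple/ordinary division mean are "simple", above the
    ordinary/complex division mean "complex", otherwise "ordinary".
    The division rows themselves carry group "division".
    """
    for div in DIVISIONS:
        if div not in distributions:
            raise ValueError(f"missing distribution for division marker {div!r}")
    rows = [{"item": d.item, "mu": d.mu, "sigma": d.sigma}
            for d in distributions.values()]
    table = pd.DataFrame(rows).sort_values(
        ["mu", "item"], kind="stable").reset_index(drop=True)
    mu1 = distributions[DIV_SIMPLE_ORDINARY].mu
    mu2 = distributions[DIV_ORDINARY_COMPLEX].mu

    def classify(row):
        if row["item"] in DIVISIONS:
            return "division"
        if row["mu"] < mu1:
            return "simple"
        if row["mu"] > mu2:
            return "complex"
        return "ordinary"

    table["group"] = table.apply(classify, axis=1)
    return table


def correlate(measure_values, mu_ranks, subset_mask=None,
              measure: str = "measure", subset: str = "all",
              alpha: float = DEFAULT_ALPHA) -> CorrelationReport:
    """Pearson correlation between an objective measure and mean ranks.

    The p-value is the two-sided t-test with n - 2 degrees of freedom;
    the least-squares line gives slope and intercept.  A subset mask
    restricts the comparison to one streetscape type.
    """
    x = np.asarray(measure_values, dtype=float)
    y = np.asarray(mu_ranks, dtype=float)
    if x.shape != y.shape:
        raise ValueError("measure and rank vectors differ in length")
    if subset_mask is not None:
        mask = np.asarray(subset_mask, dtype=bool)
        x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError(f"need at least 3 paired values, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance in input")
    res = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return CorrelationReport(measure=measure, r=float(res.statistic),
                             p_value=float(res.pvalue),
                             slope=float(fit.slope),
                             intercept=float(fit.intercept),
                             n=int(x.size), subset=subset, alpha=alpha)


def correlation_table(measures: pd.DataFrame, mu_ranks: pd.Series,
                      subsets: dict | None = None,
                      alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Correlation report for several measures over several subsets.

    ``measures`` has one column per objective measure, indexed by item;
    ``mu_ranks`` the mean subjective rank per item; ``subsets`` maps
    subset label -> boolean mask aligned with the index.
    """
    mu = mu_ranks.loc[measures.index]
    subsets = {"all": np.ones(len(measures), dtype=bool), **(subsets or {})}
    rows = []
    for label, mask in subsets.items():
        for name in measures.columns:
            rep = correlate(measures[name].to_numpy(), mu.to_numpy(),
                            subset_mask=mask, measure=name, subset=label,
                            alpha=alpha)
            rows.append({"subset": label, "measure": name, "r": rep.r,
                         "p_value": rep.p_value, "slope": rep.slope,
                         "intercept": rep.intercept, "n": rep.n,
                         "significant": rep.significant})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rank-file dialect: one CSV row per subject — subject id, then ordered item
# tokens with "|" marking each of the two group divisions.


def write_rankings(rankings, path) -> None:
    lines = []
    for rk in rankings:
        seq = [DIVISION_TOKEN if t in DIVISIONS else str(t)
               for t in rk.sequence()]
        lines.append(",".join([str(rk.subject_id)] + seq))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_rankings(path) -> list:
    """Parse the rank-file dialect back into :class:`SubjectRanking` rows."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            tokens = line.split(",")
            subject, seq = tokens[0], tokens[1:]
            if seq.count(DIVISION_TOKEN) != 2:
                raise ValueError(
                    f"line {ln}: expected exactly 2 division tokens, "
                    f"got {seq.count(DIVISION_TOKEN)}")
            i1 = seq.index(DIVISION_TOKEN)
            i2 = seq.index(DIVISION_TOKEN, i1 + 1)
            out.append(SubjectRanking(subject_id=subject, simple=seq[:i1],
                                      ordinary=seq[i1 + 1:i2],
                                      complex=seq[i2 + 1:]))
    return out
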