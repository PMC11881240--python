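"""Derived scores: HCPI, pair screening, prescription suitability, group tests.

HCPI (Herbal Combination Potential Index) is the log2(y + 1) transform of a
pair's predicted strength; pairs with HCPI strictly greater than 0.5 are
flagged high-potential. A prescription's suitability is log2(mean + 1) of the
mean predicted strength over all its unordered herb pairs. Prescriptions can
be stratified by clinical use frequency (> 10 uses vs the rest) and compared
with a two-sample t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy import stats

from .corpus import PairLabel, Prescription
from .errors import ComparisonError
from .graph import HeteroGraph
from .model import TrainedModel

#: Default HCPI screening threshold (strict inequality).
HCPI_THRESHOLD = 0.5

#: Default use-count cut for the high-frequency group (strict inequality).
FREQ_THRESHOLD = 10


def hcpi(y_hat: float) -> float:
    """log2(y_hat + 1); requires y_hat >= 0, so hcpi(0) = 0."""
    if y_hat < 0:
        raise ValueError(f"hcpi requires a nonnegative predicted strength, got {y_hat}")
    return math.log2(y_hat + 1.0)


@dataclass(frozen=True)
class PairPrediction:
    pair: tuple[str, str]
    y_hat: float
    hcpi: float
    high_potential: bool


@dataclass(frozen=True)
class PrescriptionScore:
    """Suitability of one prescription.

    ``scorable`` is False (and the score fields None) when fewer than two of
    its herbs resolve in the model vocabulary. ``oov_herbs`` lists members
    that were skipped as out-of-vocabulary.
    """

    rx_id: str
    mean_pair_value: float | None
    suitability: float | None
    frequency: int
    n_pairs: int = 0
    oov_herbs: tuple[str, ...] = ()

    @property
    def scorable(self) -> bool:
        return self.suitability is not None


@dataclass(frozen=True)
class GroupComparison:
    group_a_scores: tuple[float, ...]   # high-frequency
    group_b_scores: tuple[float, ...]   # low-frequency
    t_statistic: float
    p_value: float


def predict_all_pairs(
    model: TrainedModel,
    g: HeteroGraph,
    pairs: list[tuple[str, str]] | None = None,
    threshold: float = HCPI_THRESHOLD,
) -> list[PairPrediction]:
    """Score every unordered herb pair (or a given pair list) and attach HCPI."""
    if pairs is None:
        pairs = list(combinations(g.herb_ids, 2))
    idx = np.array(
        [[g.herb_index(a), g.herb_index(b)] for a, b in pairs], dtype=np.int64
    ).reshape(-1, 2)
    y_hat = model.predict_pairs(g, idx)
    out = []
    for (a, b), yh in zip(pairs, y_hat):
        h = hcpi(float(yh))
        pair = (a, b) if a <= b else (b, a)
        out.append(PairPrediction(pair, float(yh), h, h > threshold))
    return out


def screen_pairs(
    preds: list[PairPrediction], threshold: float = HCPI_THRESHOLD
) -> list[PairPrediction]:
    """High-potential pairs: HCPI strictly greater than the threshold,
    sorted descending by HCPI (HCPI exactly at the threshold is excluded)."""
    kept = [p for p in preds if p.hcpi > threshold]
    return sorted(kept, key=lambda p: (-p.hcpi, p.pair))


def score_prescription(
    model: TrainedModel,
    g: HeteroGraph,
    rx: Prescription,
    observed_labels: list[PairLabel] | None = None,
) -> PrescriptionScore:
    """Suitability = log2(mean pairwise strength + 1) over all C(n, 2) pairs.

    By default pair strengths are model predictions, so pairs absent from the
    training corpus still contribute; passing ``observed_labels`` switches to
    raw corpus compatibility values (pairs without a label count as 0).
    Out-of-vocabulary herbs are excluded with a warning; fewer than two
    resolvable herbs yields an unscorable record.
    """
    known = [h for h in sorted(rx.herbs) if h in g._herb_index]
    oov = tuple(h for h in sorted(rx.herbs) if h not in g._herb_index)
    if oov:
        warnings.warn(
            f"prescription {rx.rx_id}: out-of-vocabulary herbs skipped: "
            + ", ".join(oov),
            stacklevel=2,
        )
    if len(known) < 2:
        return PrescriptionScore(rx.rx_id, None, None, rx.frequency, 0, oov)
    pairs = list(combinations(known, 2))
    if observed_labels is not None:
        lookup = {l.pair: l.c_ij for l in observed_labels}
        vals = np.array([lookup.get(tuple(sorted(p)), 0.0) for p in pairs])
    else:
        idx = np.array(
            [[g.herb_index(a), g.herb_index(b)] for a, b in pairs], dtype=np.int64
        )
        vals = model.predict_pairs(g, idx)
    mean = float(np.mean(vals))
    return PrescriptionScore(
        rx.rx_id, mean, math.log2(mean + 1.0), rx.frequency, len(pairs), oov
    )


def compare_frequency_groups(
    scores: list[PrescriptionScore],
    freq_threshold: int = FREQ_THRESHOLD,
    welch: bool = True,
) -> GroupComparison:
    """Two-sample t-test of suitability between high-frequency prescriptions
    (used strictly more than ``freq_threshold`` times) and the remainder.

    Uses the Welch unequal-variance form by default; ``welch=False`` gives the
    pooled-variance test. Unscorable prescriptions are ignored.
    """
    usable = [s for s in scores if s.scorable]
    high = tuple(s.suitability for s in usable if s.frequency > freq_threshold)
    low = tuple(s.suitability for s in usable if s.frequency <= freq_threshold)
    if not high or not low:
        raise ComparisonError(
            f"both frequency groups must be non-empty (high={len(high)}, low={len(low)})"
        )
    t, p = stats.ttest_ind(high, low, equal_var=not welch)
    return GroupComparison(high, low, float(t), float(p))


def export_pair_network(
    preds: list[PairPrediction],
    graphml_path: str | Path | None = None,
    tsv_path: str | Path | None = None,
) -> None:
    """Write the prediction network (nodes = herbs, edges weighted by HCPI)
    as GraphML and/or a TSV edge list."""
    if not preds:
        raise ValueError("no predictions to export")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("herb_i\therb_j\ty_hat\thcpi\thigh_potential\n")
            for p in preds:
                fh.write(
                    f"{p.pair[0]}\t{p.pair[1]}\t{p.y_hat!r}\t{p.hcpi!r}\t"
                    f"{int(p.high_potential)}\n"
                )
    if graphml_path is not None:
        import networkx as nx

        gx = nx.Graph()
        for p in preds:
            gx.add_edge(
                p.pair[0], p.pair[1],
                weight=p.hcpi, y_hat=p.y_hat,
                high_potential=bool(p.high_potential),
            )
        nx.write_graphml(gx, graphml_path)


def read_pair_network_tsv(path: str | Path) -> list[PairPrediction]:
    """Read back the TSV written by :func:`export_pair_network`."""
    preds = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("herb_i"):
            raise ValueError(f"{path}: not a pair-network TSV")
        for line in fh:
            a, b, yh, h, hp = line.rstrip("\n").split("\t")
            preds.append(PairPrediction((a, b), float(yh), float(h), hp == "1"))
    return preds
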