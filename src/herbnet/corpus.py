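"""Prescription corpus: tables, ingredient filtering, and the compatibility statistic.

A corpus bundles the herb vocabulary, per-herb molecule annotations (with oral
bioavailability OB and drug-likeness DL values plus MACCS-style fingerprint
bits), molecule-target links, target functional-term annotations, and the
prescription list. Pairwise herb compatibility is a normalized co-occurrence
statistic over prescriptions:

    C_ij = N_ij / D * 1000,   D = sum_k n_k (n_k - 1) / 2

where ``N_ij`` counts prescriptions containing both herbs and ``n_k`` is the
size of prescription ``k``. Because each prescription of size ``n_k``
contributes exactly ``C(n_k, 2)`` pair co-occurrences, the C_ij of all
unordered pairs sum to 1000 exactly.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd

from .errors import DegenerateCorpusError, ReferentialError, SchemaError

logger = logging.getLogger(__name__)

# Inclusive pharmacokinetic screening thresholds: molecules are retained when
# oral bioavailability >= 30 (percent scale) and drug-likeness >= 0.18.
OB_MIN_DEFAULT = 30.0
DL_MIN_DEFAULT = 0.18

#: Standard MACCS key count.
DEFAULT_FINGERPRINT_BITS = 166


@dataclass(frozen=True)
class Herb:
    herb_id: str
    display_name: str = ""


@dataclass(frozen=True)
class Molecule:
    """Small molecule with screening properties and a binary fingerprint.

    ``ob`` is percent-scale oral bioavailability (>= 0); ``dl`` is
    drug-likeness in [0, 1]; ``fingerprint`` is a frozenset of set-bit indices
    into a fixed-length MACCS-style key vector.
    """

    mol_id: str
    ob: float
    dl: float
    fingerprint: frozenset[int] = frozenset()

    def __post_init__(self):
        if not (math.isfinite(self.ob) and math.isfinite(self.dl)):
            raise SchemaError(f"molecule {self.mol_id}: ob/dl must be finite")


@dataclass(frozen=True)
class TargetGene:
    """Target gene annotated with a set of functional-term ids (GO-like)."""

    target_id: str
    terms: frozenset[str] = frozenset()


@dataclass(frozen=True)
class Prescription:
    """One prescription: a set of herb ids plus an optional clinical use count."""

    rx_id: str
    herbs: frozenset[str]
    frequency: int = 1

    @property
    def size(self) -> int:
        return len(self.herbs)


@dataclass(frozen=True)
class PairLabel:
    """Compatibility label for one unordered herb pair.

    ``pair`` is stored sorted so (i, j) and (j, i) map to the same label.
    """

    pair: tuple[str, str]
    n_ij: int
    c_ij: float

    def __post_init__(self):
        if self.pair[0] > self.pair[1]:
            object.__setattr__(self, "pair", (self.pair[1], self.pair[0]))
        if (self.c_ij == 0) != (self.n_ij == 0):
            raise ValueError("c_ij must be zero exactly when n_ij is zero")


@dataclass
class Corpus:
    herbs: dict[str, Herb]
    molecules: dict[str, Molecule]
    targets: dict[str, TargetGene]
    prescriptions: list[Prescription]
    herb_mol_links: set[tuple[str, str]] = field(default_factory=set)
    mol_target_links: set[tuple[str, str]] = field(default_factory=set)
    fingerprint_bits: int = DEFAULT_FINGERPRINT_BITS
    term_vocab: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.term_vocab:
            vocab = sorted({t for tg in self.targets.values() for t in tg.terms})
            self.term_vocab = tuple(vocab)
        self.validate()

    def validate(self) -> None:
        if len(self.prescriptions) < 1:
            raise SchemaError("corpus must contain at least one prescription")
        bad = sorted(
            {h for rx in self.prescriptions for h in rx.herbs if h not in self.herbs}
        )
        if bad:
            raise ReferentialError(
                f"prescriptions reference unknown herb ids: {', '.join(bad)}"
            )
        for h, m in self.herb_mol_links:
            if h not in self.herbs:
                raise ReferentialError(f"herb_mol link references unknown herb {h!r}")
            if m not in self.molecules:
                raise ReferentialError(f"herb_mol link references unknown molecule {m!r}")
        for m, t in self.mol_target_links:
            if m not in self.molecules:
                raise ReferentialError(f"mol_target link references unknown molecule {m!r}")
            if t not in self.targets:
                raise ReferentialError(f"mol_target link references unknown target {t!r}")
        for mol in self.molecules.values():
            if mol.fingerprint and max(mol.fingerprint) >= self.fingerprint_bits:
                raise SchemaError(
                    f"molecule {mol.mol_id}: fingerprint bit out of range "
                    f"(length {self.fingerprint_bits})"
                )

    @property
    def n_prescriptions(self) -> int:
        return len(self.prescriptions)


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

_REQUIRED = {
    "prescriptions": ("rx_id", "herb_id"),
    "herbs": ("herb_id",),
    "molecules": ("mol_id", "ob", "dl"),
    "herb_mol": ("herb_id", "mol_id"),
    "mol_target": ("mol_id", "target_id"),
    "targets": ("target_id",),
}


def _read_table(path: str | Path, kind: str, sep: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{kind} table not found: {path}")
    if sep is None:
        # dialect auto-detect from the header (comma default, tab accepted);
        # a csv sniffer chokes on single-column tables
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in _REQUIRED[kind] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{kind} table {path} is missing required column(s): {', '.join(missing)}"
        )
    return df


def _parse_joined(cell, cast=str) -> frozenset:
    """Parse a semicolon-joined cell ('1;5;9') into a frozenset."""
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return frozenset()
    return frozenset(cast(tok) for tok in str(cell).split(";") if tok != "")


def read_corpus(
    prescription_path: str | Path,
    herbs_path: str | Path,
    molecules_path: str | Path | None = None,
    herb_mol_path: str | Path | None = None,
    mol_target_path: str | Path | None = None,
    targets_path: str | Path | None = None,
    sep: str | None = None,
    fingerprint_bits: int = DEFAULT_FINGERPRINT_BITS,
) -> Corpus:
    """Read and validate a corpus from long-format CSV/TSV tables.

    ``prescriptions``: one row per prescription-herb membership (columns
    rx_id, herb_id, optional frequency). Annotation tables are optional; an
    absent table yields the corresponding empty relation. ``sep=None``
    auto-detects comma vs tab.

    Prescriptions with identical herb sets are collapsed to a single record
    (the first occurrence is retained), so a study entered twice contributes
    once to the co-occurrence statistic.
    """
    rx_df = _read_table(prescription_path, "prescriptions", sep)
    herb_df = _read_table(herbs_path, "herbs", sep)

    herbs = {
        str(r.herb_id): Herb(str(r.herb_id), str(getattr(r, "display_name", r.herb_id)))
        for r in herb_df.itertuples()
    }

    prescriptions: list[Prescription] = []
    seen_sets: set[frozenset[str]] = set()
    has_freq = "frequency" in rx_df.columns
    for rx_id, grp in rx_df.groupby("rx_id", sort=False):
        herb_set = frozenset(grp["herb_id"].astype(str))
        if herb_set in seen_sets:
            logger.info("prescription %s duplicates an earlier herb set; dropped", rx_id)
            continue
        seen_sets.add(herb_set)
        freq = 1
        if has_freq:
            f0 = grp["frequency"].dropna()
            if len(f0):
                freq = int(float(f0.iloc[0]))
        prescriptions.append(Prescription(str(rx_id), herb_set, freq))

    molecules: dict[str, Molecule] = {}
    if molecules_path is not None:
        mol_df = _read_table(molecules_path, "molecules", sep)
        for r in mol_df.itertuples():
            fp = _parse_joined(getattr(r, "fp_bits", None), int)
            molecules[str(r.mol_id)] = Molecule(
                str(r.mol_id), float(r.ob), float(r.dl), fp
            )

    targets: dict[str, TargetGene] = {}
    if targets_path is not None:
        tgt_df = _read_table(targets_path, "targets", sep)
        for r in tgt_df.itertuples():
            terms = _parse_joined(getattr(r, "term_ids", None))
            targets[str(r.target_id)] = TargetGene(str(r.target_id), terms)

    herb_mol: set[tuple[str, str]] = set()
    if herb_mol_path is not None:
        hm_df = _read_table(herb_mol_path, "herb_mol", sep)
        herb_mol = {(str(r.herb_id), str(r.mol_id)) for r in hm_df.itertuples()}

    mol_target: set[tuple[str, str]] = set()
    if mol_target_path is not None:
        mt_df = _read_table(mol_target_path, "mol_target", sep)
        mol_target = {(str(r.mol_id), str(r.target_id)) for r in mt_df.itertuples()}

    return Corpus(
        herbs=herbs,
        molecules=molecules,
        targets=targets,
        prescriptions=prescriptions,
        herb_mol_links=herb_mol,
        mol_target_links=mol_target,
        fingerprint_bits=fingerprint_bits,
    )


def write_corpus(corpus: Corpus, out_dir: str | Path) -> dict[str, Path]:
    """Write a corpus back to the CSV schemas ``read_corpus`` accepts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rx_rows = [
        {"rx_id": rx.rx_id, "herb_id": h, "frequency": rx.frequency}
        for rx in corpus.prescriptions
        for h in sorted(rx.herbs)
    ]
    paths["prescriptions"] = out / "prescriptions.csv"
    pd.DataFrame(rx_rows).to_csv(paths["prescriptions"], index=False)

    paths["herbs"] = out / "herbs.csv"
    pd.DataFrame(
        [{"herb_id": h.herb_id, "display_name": h.display_name}
         for h in corpus.herbs.values()]
    ).to_csv(paths["herbs"], index=False)

    paths["molecules"] = out / "molecules.csv"
    pd.DataFrame(
        [{"mol_id": m.mol_id, "ob": m.ob, "dl": m.dl,
          "fp_bits": ";".join(str(b) for b in sorted(m.fingerprint))}
         for m in corpus.molecules.values()]
    ).to_csv(paths["molecules"], index=False)

    paths["targets"] = out / "targets.csv"
    pd.DataFrame(
        [{"target_id": t.target_id, "term_ids": ";".join(sorted(t.terms))}
         for t in corpus.targets.values()]
    ).to_csv(paths["targets"], index=False)

    paths["herb_mol"] = out / "herb_mol.csv"
    pd.DataFrame(sorted(corpus.herb_mol_links), columns=["herb_id", "mol_id"]).to_csv(
        paths["herb_mol"], index=False
    )
    paths["mol_target"] = out / "mol_target.csv"
    pd.DataFrame(sorted(corpus.mol_target_links), columns=["mol_id", "target_id"]).to_csv(
        paths["mol_target"], index=False
    )
    return paths


# ---------------------------------------------------------------------------
# Filtering and compatibility
# ---------------------------------------------------------------------------


def filter_molecules(
    corpus: Corpus, ob_min: float = OB_MIN_DEFAULT, dl_min: float = DL_MIN_DEFAULT
) -> Corpus:
    """Retain molecules with ob >= ob_min AND dl >= dl_min (both inclusive).

    Links whose molecule was removed are dropped; herbs, targets and
    prescriptions are untouched. Idempotent.
    """
    if not (math.isfinite(ob_min) and math.isfinite(dl_min)):
        raise ValueError("thresholds must be finite")
    kept = {
        mid: m for mid, m in corpus.molecules.items()
        if m.ob >= ob_min and m.dl >= dl_min
    }
    if corpus.molecules and not kept:
        logger.warning("filter_molecules removed every molecule (ob>=%s, dl>=%s)",
                       ob_min, dl_min)
    return Corpus(
        herbs=dict(corpus.herbs),
        molecules=kept,
        targets=dict(corpus.targets),
        prescriptions=list(corpus.prescriptions),
        herb_mol_links={(h, m) for h, m in corpus.herb_mol_links if m in kept},
        mol_target_links={(m, t) for m, t in corpus.mol_target_links if m in kept},
        fingerprint_bits=corpus.fingerprint_bits,
        term_vocab=corpus.term_vocab,
    )


def cooccurrence_counts(corpus: Corpus) -> dict[tuple[str, str], int]:
    """Count, per unordered herb pair, the number of prescriptions containing both.

    Each prescription of size n contributes +1 to each of its C(n, 2) pairs.
    Pairs that never co-occur are absent from the map.
    """
    counts: Counter[tuple[str, str]] = Counter()
    for rx in corpus.prescriptions:
        for a, b in combinations(sorted(rx.herbs), 2):
            counts[(a, b)] += 1
    return dict(counts)


def pair_denominator(corpus: Corpus) -> int:
    """Total number of pair slots D = sum_k n_k (n_k - 1) / 2."""
    return sum(rx.size * (rx.size - 1) // 2 for rx in corpus.prescriptions)


def compatibility(corpus: Corpus) -> list[PairLabel]:
    """Compute C_ij = N_ij / D * 1000 for every co-occurring unordered pair.

    Raises :class:`DegenerateCorpusError` when every prescription is a
    singleton (D = 0). The returned labels sum to 1000 over all pairs.
    """
    d = pair_denominator(corpus)
    if d == 0:
        raise DegenerateCorpusError(
            "all prescriptions are singletons; the compatibility denominator is zero"
        )
    counts = cooccurrence_counts(corpus)
    return [
        PairLabel(pair=pair, n_ij=n, c_ij=n / d * 1000.0)
        for pair, n in sorted(counts.items())
    ]


def pair_labels_to_frame(labels: list[PairLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"herb_i": l.pair[0], "herb_j": l.pair[1], "n_ij": l.n_ij, "c_ij": l.c_ij}
         for l in labels]
    )


def pair_labels_from_frame(df: pd.DataFrame) -> list[PairLabel]:
    need = {"herb_i", "herb_j", "n_ij", "c_ij"}
    missing = need - set(df.columns)
    if missing:
        raise SchemaError(f"pair-label table missing column(s): {', '.join(sorted(missing))}")
    return [
        PairLabel((str(r.herb_i), str(r.herb_j)), int(r.n_ij), float(r.c_ij))
        for r in df.itertuples()
    ]
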