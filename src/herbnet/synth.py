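"""Synthetic prescription corpora with planted co-occurrence block structure.

The generator emulates the shape of a curated herbal-pharmacology corpus: a
herb vocabulary partitioned into latent communities ("blocks"), prescriptions
drawn by seeding a block and sampling members with boosted within-block odds,
a shared molecule pool with oral-bioavailability / drug-likeness values
straddling the 30 / 0.18 screening thresholds, sparse MACCS-style
fingerprints, molecule-target links and target functional-term annotations.
Default sizes mirror a realistic curated corpus: 122 herbs, 72 prescriptions,
and enough molecules/targets that roughly 234 molecules and 657 targets
remain in the annotated graph after pharmacokinetic filtering.

Everything is deterministic under the config seed. The planted block
structure is the ground truth that the full pipeline (compatibility -> graph
-> training -> screening) must recover: within-block pairs co-occur more,
get higher compatibility scores, and should receive higher predicted
strengths than between-block pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import (
    Corpus,
    DEFAULT_FINGERPRINT_BITS,
    Herb,
    Molecule,
    Prescription,
    TargetGene,
)


@dataclass
class SynthConfig:
    n_herbs: int = 122
    n_prescriptions: int = 72
    rx_size_range: tuple[int, int] = (5, 15)
    n_blocks: int = 4
    within_block_boost: float = 5.0
    n_molecules: int = 360
    n_molecules_per_herb: tuple[int, int] = (12, 24)
    fingerprint_bits: int = DEFAULT_FINGERPRINT_BITS
    fingerprint_density: float = 0.1
    n_targets: int = 657
    n_targets_per_mol: tuple[int, int] = (60, 115)
    n_terms: int = 40
    n_terms_per_target: tuple[int, int] = (1, 8)
    ob_dl_pass_fraction: float = 0.65
    frequency_distribution: dict = field(
        default_factory=lambda: {"kind": "geometric", "p": 0.15}
    )
    oov_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("rx_size_range", "n_molecules_per_herb",
                     "n_targets_per_mol", "n_terms_per_target"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} must be an ordered nonnegative range")
        if self.rx_size_range[1] > self.n_herbs:
            raise ValueError("rx_size_range max exceeds the herb vocabulary")
        for name in ("fingerprint_density", "ob_dl_pass_fraction"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.within_block_boost < 1:
            raise ValueError("within_block_boost must be >= 1")
        if not (0 <= self.oov_fraction < 1):
            raise ValueError("oov_fraction must be in [0, 1)")


def block_assignment(cfg: SynthConfig) -> dict[str, int]:
    """Deterministic herb -> block map (contiguous, nearly equal blocks)."""
    return {
        _herb_id(i): i * cfg.n_blocks // cfg.n_herbs for i in range(cfg.n_herbs)
    }


def _herb_id(i: int) -> str:
    return f"H{i:03d}"


def _draw_range(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def generate_corpus(cfg: SynthConfig) -> Corpus:
    """Generate a full corpus (herbs, prescriptions, annotations) from a config.

    Prescriptions are drawn by picking a seed block uniformly, then sampling
    herbs without replacement with selection odds multiplied by
    ``within_block_boost`` for herbs in the seed block. Molecules pass the
    OB >= 30 / DL >= 0.18 screen with probability ``ob_dl_pass_fraction``;
    failing molecules miss one or both thresholds.
    """
    rng = np.random.default_rng(cfg.seed)
    herbs = {
        _herb_id(i): Herb(_herb_id(i), f"Herb {i:03d}") for i in range(cfg.n_herbs)
    }
    blocks = block_assignment(cfg)
    block_idx = np.array([blocks[_herb_id(i)] for i in range(cfg.n_herbs)])

    prescriptions = []
    for k in range(cfg.n_prescriptions):
        size = _draw_range(rng, cfg.rx_size_range)
        seed_block = int(rng.integers(cfg.n_blocks))
        w = np.where(block_idx == seed_block, cfg.within_block_boost, 1.0)
        members = rng.choice(cfg.n_herbs, size=size, replace=False, p=w / w.sum())
        prescriptions.append(
            Prescription(f"RX{k:04d}", frozenset(_herb_id(i) for i in members))
        )

    molecules = {}
    for j in range(cfg.n_molecules):
        mid = f"M{j:04d}"
        if rng.random() < cfg.ob_dl_pass_fraction:
            ob = float(rng.uniform(30.0, 100.0))
            dl = float(rng.uniform(0.18, 1.0))
        else:
            mode = rng.integers(3)   # fail OB, fail DL, or fail both
            ob = float(rng.uniform(1.0, 29.5)) if mode in (0, 2) else float(
                rng.uniform(30.0, 100.0))
            dl = float(rng.uniform(0.01, 0.17)) if mode in (1, 2) else float(
                rng.uniform(0.18, 1.0))
        n_bits = rng.binomial(cfg.fingerprint_bits, cfg.fingerprint_density)
        fp = frozenset(
            int(b) for b in rng.choice(cfg.fingerprint_bits, size=n_bits,
                                       replace=False)
        )
        molecules[mid] = Molecule(mid, ob, dl, fp)

    mol_ids = sorted(molecules)
    herb_mol = set()
    for i in range(cfg.n_herbs):
        k = min(_draw_range(rng, cfg.n_molecules_per_herb), cfg.n_molecules)
        for j in rng.choice(cfg.n_molecules, size=k, replace=False):
            herb_mol.add((_herb_id(i), mol_ids[j]))

    terms = [f"T{u:03d}" for u in range(cfg.n_terms)]
    targets = {}
    for t in range(cfg.n_targets):
        tid = f"G{t:04d}"
        k = min(_draw_range(rng, cfg.n_terms_per_target), cfg.n_terms)
        tset = frozenset(
            terms[u] for u in rng.choice(cfg.n_terms, size=k, replace=False)
        )
        targets[tid] = TargetGene(tid, tset)

    tgt_ids = sorted(targets)
    mol_target = set()
    for j in range(cfg.n_molecules):
        k = min(_draw_range(rng, cfg.n_targets_per_mol), cfg.n_targets)
        for t in rng.choice(cfg.n_targets, size=k, replace=False):
            mol_target.add((mol_ids[j], tgt_ids[t]))

    return Corpus(
        herbs=herbs,
        molecules=molecules,
        targets=targets,
        prescriptions=prescriptions,
        herb_mol_links=herb_mol,
        mol_target_links=mol_target,
        fingerprint_bits=cfg.fingerprint_bits,
    )


def generate_clinical_records(
    corpus: Corpus, n_records: int, cfg: SynthConfig
) -> list[Prescription]:
    """Simulate clinical prescription records over the corpus herb vocabulary.

    Records reuse the corpus herbs (with the same block-structured
    co-selection) but a fraction ``cfg.oov_fraction`` of member slots are
    replaced by out-of-vocabulary herbs, and each record carries a long-tailed
    clinical use count drawn from ``cfg.frequency_distribution``, so both the
    high-frequency (> 10 uses) and low-frequency strata are populated.
    """
    rng = np.random.default_rng([cfg.seed, 9001])
    herb_ids = sorted(corpus.herbs)
    n = len(herb_ids)
    blocks = block_assignment(cfg)
    block_idx = np.array([blocks.get(h, 0) for h in herb_ids])
    dist = cfg.frequency_distribution

    records = []
    for r in range(n_records):
        size = min(_draw_range(rng, cfg.rx_size_range), n)
        seed_block = int(rng.integers(cfg.n_blocks))
        w = np.where(block_idx == seed_block, cfg.within_block_boost, 1.0)
        members = [
            herb_ids[i]
            for i in rng.choice(n, size=size, replace=False, p=w / w.sum())
        ]
        members = [
            f"OOV{rng.integers(1000):03d}" if rng.random() < cfg.oov_fraction else h
            for h in members
        ]
        if dist.get("kind", "geometric") == "geometric":
            freq = int(rng.geometric(dist.get("p", 0.15)))
        else:
            raise ValueError(f"unknown frequency distribution {dist!r}")
        records.append(Prescription(f"CRX{r:05d}", frozenset(members), freq))
    return records
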