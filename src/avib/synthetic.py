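"""Seeded synthetic interaction data with the statistical structure the
model assumes.

The generator emulates the defining property of receptor–ligand recognition
data: no single sequence is informative about the label on its own — only the
joint (peptide, CDR3) pattern is. Each of C latent binding classes owns a
peptide motif and a cognate CDR3 motif; a record binds iff its peptide's
class matches its CDR3s' class. Class frequencies are arranged to be
label-independent per sequence (the peptide class marginal is uniform among
binders and among non-binders, and likewise for the CDR3 class), so any
single-sequence classifier is reduced to chance up to motif-overlap noise.
Motifs are implanted at random positions over a uniform residue background;
labels are flipped with probability eta.

Out-of-distribution sequences come from a shifted residue composition and/or
a disjoint length range, with no implanted in-distribution motifs — the
synthetic analogue of scoring foreign-species receptor sequences against a
model trained on one species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import CANONICAL_RESIDUES, AminoAcidSequence, Role
from .model import SequenceRecord

__all__ = [
    "GeneratorConfig",
    "generate_interaction_dataset",
    "generate_ood_sequences",
    "generate_regression_dataset",
    "class_motifs",
    "match_strength",
]

#: Residues heavily up-weighted in the composition-shifted OOD background.
OOD_RESIDUE_SUBSET = "WYFHM"


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic interaction generator."""

    n_records: int = 5000
    peptide_length: tuple = (8, 15)
    cdr3_length: tuple = (10, 20)
    n_classes: int = 4
    motif_length: int = 3
    label_noise: float = 0.05
    positive_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if min(self.peptide_length) < 1 or min(self.cdr3_length) < 1:
            raise ValueError("lengths must be positive")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must lie in (0, 1)")
        if self.motif_length > min(self.peptide_length):
            raise ValueError("motif longer than the shortest peptide")
        if self.motif_length > min(self.cdr3_length):
            raise ValueError("motif longer than the shortest CDR3")
        if self.n_classes < 2:
            raise ValueError("need at least 2 binding classes")


def _class_motifs(n_classes: int, motif_length: int, rng: np.random.Generator):
    """Per-class (peptide motif, CDR3 motif) pairs, distinct across classes."""
    motifs = set()
    pep, cdr = [], []
    while len(pep) < n_classes:
        m = "".join(rng.choice(list(CANONICAL_RESIDUES), size=motif_length))
        if m not in motifs:
            motifs.add(m)
            pep.append(m)
    while len(cdr) < n_classes:
        m = "".join(rng.choice(list(CANONICAL_RESIDUES), size=motif_length))
        if m not in motifs:
            motifs.add(m)
            cdr.append(m)
    return pep, cdr


def class_motifs(cfg: GeneratorConfig):
    """The (peptide motifs, CDR3/MHC motifs) a given config implants — the
    ground truth used by generator audits and oracle regressors."""
    return _class_motifs(cfg.n_classes, cfg.motif_length, np.random.default_rng(cfg.seed))


def _background(length: int, rng: np.random.Generator, weights=None) -> str:
    letters = rng.choice(list(CANONICAL_RESIDUES), size=length, p=weights)
    return "".join(letters)


def _implant(background: str, motif: str, rng: np.random.Generator) -> str:
    pos = rng.integers(0, len(background) - len(motif) + 1)
    return background[:pos] + motif + background[pos + len(motif) :]


def generate_interaction_dataset(cfg: GeneratorConfig) -> list[SequenceRecord]:
    """Binary (peptide, CDR3α, CDR3β) records where only the joint pattern
    carries the label; deterministic given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    pep_motifs, cdr_motifs = _class_motifs(cfg.n_classes, cfg.motif_length, rng)
    records = []
    for i in range(cfg.n_records):
        binder = rng.random() < cfg.positive_fraction
        pep_class = int(rng.integers(cfg.n_classes))
        if binder:
            cdr_class = pep_class
        else:
            offset = int(rng.integers(1, cfg.n_classes))
            cdr_class = (pep_class + offset) % cfg.n_classes
        pep_len = int(rng.integers(cfg.peptide_length[0], cfg.peptide_length[1] + 1))
        a_len = int(rng.integers(cfg.cdr3_length[0], cfg.cdr3_length[1] + 1))
        b_len = int(rng.integers(cfg.cdr3_length[0], cfg.cdr3_length[1] + 1))
        pep = _implant(_background(pep_len, rng), pep_motifs[pep_class], rng)
        cdr3a = _implant(_background(a_len, rng), cdr_motifs[cdr_class], rng)
        cdr3b = _implant(_background(b_len, rng), cdr_motifs[cdr_class], rng)
        label = float(binder)
        if rng.random() < cfg.label_noise:
            label = 1.0 - label
        records.append(
            SequenceRecord(
                sequences={
                    Role.PEPTIDE: AminoAcidSequence(pep, Role.PEPTIDE),
                    Role.CDR3A: AminoAcidSequence(cdr3a, Role.CDR3A),
                    Role.CDR3B: AminoAcidSequence(cdr3b, Role.CDR3B),
                },
                label=label,
                sample_id=f"id_{i:06d}",
            )
        )
    return records


def generate_ood_sequences(
    n: int,
    shift: str = "composition",
    seed: int = 0,
    cfg: GeneratorConfig | None = None,
) -> list[SequenceRecord]:
    """Records from a shifted distribution: residue composition re-weighted
    toward a disjoint subset ('composition'), lengths outside the ID range
    ('length'), or both. No ID motifs are implanted. The label field is
    populated with the same Bernoulli rule but is never used for scoring —
    detection is unsupervised.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if shift not in ("composition", "length", "both"):
        raise ValueError(f"unknown shift {shift!r}")
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)
    weights = None
    if shift in ("composition", "both"):
        w = np.full(len(CANONICAL_RESIDUES), 1.0)
        for ch in OOD_RESIDUE_SUBSET:
            w[CANONICAL_RESIDUES.index(ch)] = 15.0
        weights = w / w.sum()
    if shift in ("length", "both"):
        pep_rng = (cfg.peptide_length[1] + 3, cfg.peptide_length[1] + 8)
        cdr_rng = (cfg.cdr3_length[1] + 3, cfg.cdr3_length[1] + 8)
    else:
        pep_rng, cdr_rng = cfg.peptide_length, cfg.cdr3_length
    records = []
    for i in range(n):
        pep_len = int(rng.integers(pep_rng[0], pep_rng[1] + 1))
        a_len = int(rng.integers(cdr_rng[0], cdr_rng[1] + 1))
        b_len = int(rng.integers(cdr_rng[0], cdr_rng[1] + 1))
        records.append(
            SequenceRecord(
                sequences={
                    Role.PEPTIDE: AminoAcidSequence(
                        _background(pep_len, rng, weights), Role.PEPTIDE
                    ),
                    Role.CDR3A: AminoAcidSequence(
                        _background(a_len, rng, weights), Role.CDR3A
                    ),
                    Role.CDR3B: AminoAcidSequence(
                        _background(b_len, rng, weights), Role.CDR3B
                    ),
                },
                label=float(rng.random() < cfg.positive_fraction),
                sample_id=f"ood_{i:06d}",
            )
        )
    return records


def match_strength(a: str, b_motif: str) -> int:
    """Longest common contiguous overlap between a sequence and a motif."""
    best = 0
    for k in range(len(b_motif), 0, -1):
        for s in range(len(b_motif) - k + 1):
            if b_motif[s : s + k] in a:
                best = max(best, k)
                break
        if best:
            break
    return best


def generate_regression_dataset(
    cfg: GeneratorConfig, noise_sd: float = 0.05, return_latent: bool = False
) -> list[SequenceRecord]:
    """(peptide, MHC pseudo-sequence) records with a continuous binding
    affinity in [0, 1]: a logistic function of the motif-match strength
    between the two sequences plus Gaussian noise, clipped to [0, 1].

    return_latent=True additionally returns the array of true match
    fractions, for generator audits and oracle regressors.
    """
    rng = np.random.default_rng(cfg.seed)
    latent = []
    pep_motifs, mhc_motifs = _class_motifs(cfg.n_classes, cfg.motif_length, rng)
    records = []
    for i in range(cfg.n_records):
        pep_class = int(rng.integers(cfg.n_classes))
        # match fraction in [0, 1]: how much of the cognate motif the MHC carries
        frac = rng.integers(0, cfg.motif_length + 1) / cfg.motif_length
        pep_len = int(rng.integers(cfg.peptide_length[0], cfg.peptide_length[1] + 1))
        mhc_len = int(rng.integers(cfg.cdr3_length[0], cfg.cdr3_length[1] + 1))
        pep = _implant(_background(pep_len, rng), pep_motifs[pep_class], rng)
        k = int(round(frac * cfg.motif_length))
        mhc = _background(mhc_len, rng)
        if k > 0:
            mhc = _implant(mhc, mhc_motifs[pep_class][:k], rng)
        affinity = 1.0 / (1.0 + np.exp(-6.0 * (frac - 0.5)))
        label = float(np.clip(affinity + rng.normal(0.0, noise_sd), 0.0, 1.0))
        latent.append(frac)
        records.append(
            SequenceRecord(
                sequences={
                    Role.PEPTIDE: AminoAcidSequence(pep, Role.PEPTIDE),
                    Role.MHC_PSEUDO: AminoAcidSequence(mhc, Role.MHC_PSEUDO),
                },
                label=label,
                sample_id=f"ba_{i:06d}",
            )
        )
    if return_latent:
        return records, np.asarray(latent)
    return records
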