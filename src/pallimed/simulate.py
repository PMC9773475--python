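"""Synthetic cohort generator with planted statistical structure.

No EHR corpus ships with this package, so every pipeline stage is
exercised on generated data: a cohort of patients with two latent
groups (early-integration vs late-referral), right-skewed
referral-to-death intervals, per-drug mention probabilities that
differ between the groups, planted co-prescription pairs, and noisy
note text in which drug mentions (canonical names or brand synonyms)
are embedded among filler tokens.

Defaults emulate the study conditions the pipeline targets: 119
patients, a 22-day median interval, log-normal intervals (the
distribution is right-skewed; the two latent groups' medians are
placed symmetrically around the target on the log scale so the
mixture median equals it), and per-drug probabilities derived from
the reference frequency table (frequency / group size at group sizes
61 and 58), plus the micafungin/voriconazole co-prescription pair.

Everything is driven by one integer seed; the same seed reproduces
the cohort bit for bit.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .cohort import PatientRecord, write_cohort_csv
from .extract import NoteDocument, write_notes
from .lexicon import DrugLexicon, load_default_lexicon

__all__ = [
    "DrugProfile",
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "write_cohort",
    "default_drug_profiles",
]


@dataclass(frozen=True)
class DrugProfile:
    """Per-drug mention probabilities in the two latent groups."""

    term: str
    p_early: float
    p_late: float

    def __post_init__(self) -> None:
        for p in (self.p_early, self.p_late):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.term}: probability {p} outside [0, 1]")

    @property
    def enrichment(self) -> float:
        """Planted trigger strength: p_early * (p_early - p_late)."""
        return self.p_early * (self.p_early - self.p_late)


# Reference frequencies (early n=61, late n=58) behind the default
# profiles: (term, freq_early, freq_late).
_REFERENCE_FREQS = [
    ("cefepime", 35, 19),
    ("fluconazole", 25, 8),
    ("vancomycin", 22, 5),
    ("ceftazidime", 21, 4),
    ("furosemide", 23, 8),
    ("morphine", 29, 19),
    ("albumin", 23, 11),
    ("amiodarone", 23, 12),
    ("fentanyl", 19, 8),
    ("meropenem", 16, 4),
    ("metronidazole", 16, 4),
]

# Drugs without a group contrast, to populate the networks.
_BACKGROUND = [
    ("micafungin", 0.16, 0.05),
    ("voriconazole", 0.14, 0.05),
    ("lidocaine", 0.11, 0.07),
    ("alprazolam", 0.12, 0.07),
    ("linezolid", 0.12, 0.05),
    ("piperacillin", 0.10, 0.26),
    ("penicillin", 0.08, 0.21),
    ("bevacizumab", 0.03, 0.12),
    ("capecitabine", 0.03, 0.12),
    ("scopolamine", 0.05, 0.12),
    ("hydrocortisone", 0.15, 0.24),
    ("midazolam", 0.50, 0.50),
    ("propofol", 0.40, 0.40),
    ("norepinephrine", 0.60, 0.60),
    ("heparin", 0.40, 0.40),
    ("pantoprazole", 0.45, 0.45),
    ("insulin", 0.35, 0.35),
    ("acetaminophen", 0.40, 0.40),
]


def default_drug_profiles() -> list[DrugProfile]:
    """Study-calibrated mention probabilities for ~30 ICU drugs."""
    profiles = [
        DrugProfile(term, fe / 61.0, fl / 58.0) for term, fe, fl in _REFERENCE_FREQS
    ]
    profiles.extend(DrugProfile(t, pe, pl) for t, pe, pl in _BACKGROUND)
    return profiles


# filler vocabulary base: generic ward-note words, no drug names
_FILLER_BASE = (
    "patient stable afebrile overnight family meeting discussed goals care "
    "comfort ventilator settings weaned secretions suction oxygen saturation "
    "blood pressure heart rate rhythm sinus labs pending chest film clear "
    "abdomen soft bowel sounds present urine output adequate skin intact "
    "edema noted bilateral lower limbs neuro exam unchanged sedation hold "
    "daily awakening trial spontaneous breathing nursing reports restful "
    "night pain score controlled prn given infusion rate titrated continue "
    "current plan monitor reassess tomorrow social worker consulted chaplain "
    "visited spouse bedside children informed prognosis guarded condition "
    "critical transfer hospice discussed consent signed orders updated diet "
    "npo tube feeds tolerated residuals minimal wound dressing changed"
).split()


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Parameters
    ----------
    n_patients : int
        Cohort size (>= 2).
    median_interval_days : float
        Target median referral-to-death interval of the mixture.
    interval_dispersion : float
        Log-normal sigma of each latent group's interval distribution.
    group_separation : float
        Ratio by which the latent-early median exceeds (and the
        latent-late median falls below) the target, on the log scale;
        larger values mean the realized median split recovers the
        latent groups more purely.
    drug_profiles : sequence of DrugProfile, optional
        Defaults to :func:`default_drug_profiles`.
    coprescription_pairs : sequence of (term_a, term_b, joint_boost)
        With probability ``joint_boost`` a patient receives both
        drugs of the pair jointly (on top of independent draws).
    notes_per_patient : (int, int)
        Inclusive range of notes per patient.
    filler_vocab_size : int
        Number of distinct non-drug filler tokens.
    synonym_usage_rate : float
        Probability that a mention uses a brand synonym from the
        lexicon instead of the canonical name.
    seed : int
        Mandatory; the only source of randomness.
    """

    seed: int
    n_patients: int = 119
    median_interval_days: float = 22.0
    interval_dispersion: float = 0.8
    group_separation: float = 2.2
    drug_profiles: Optional[Sequence[DrugProfile]] = None
    coprescription_pairs: Sequence[tuple[str, str, float]] = (
        ("micafungin", "voriconazole", 0.25),
    )
    notes_per_patient: tuple[int, int] = (2, 4)
    filler_vocab_size: int = 150
    synonym_usage_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.median_interval_days <= 0:
            raise ValueError("median_interval_days must be positive")
        if self.interval_dispersion <= 0 or self.group_separation < 1:
            raise ValueError("dispersion must be > 0 and separation >= 1")
        if not 0.0 <= self.synonym_usage_rate <= 1.0:
            raise ValueError("synonym_usage_rate outside [0, 1]")
        lo, hi = self.notes_per_patient
        if lo < 1 or hi < lo:
            raise ValueError("notes_per_patient must be a range with lo >= 1")
        for a, b, boost in self.coprescription_pairs:
            if not 0.0 <= boost <= 1.0:
                raise ValueError(f"joint_boost for ({a}, {b}) outside [0, 1]")

    def resolved_profiles(self) -> list[DrugProfile]:
        """Profiles with pair members auto-added at a small base rate."""
        profiles = list(self.drug_profiles) if self.drug_profiles is not None else default_drug_profiles()
        known = {p.term for p in profiles}
        for a, b, _ in self.coprescription_pairs:
            for term in (a, b):
                if term not in known:
                    profiles.append(DrugProfile(term, 0.05, 0.05))
                    known.add(term)
        return profiles


@dataclass
class SyntheticCohort:
    """Generated patients, notes, and the planted ground truth."""

    patients: list[PatientRecord]
    notes: list[NoteDocument]
    truth: dict

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]


def _filler_vocab(size: int, lexicon: DrugLexicon) -> list[str]:
    """Deterministic filler words, guaranteed not to match the lexicon."""
    vocab: list[str] = []
    i = 0
    while len(vocab) < size:
        if i < len(_FILLER_BASE):
            word = _FILLER_BASE[i]
        else:
            word = f"{_FILLER_BASE[i % len(_FILLER_BASE)]}{i // len(_FILLER_BASE)}"
        i += 1
        if word not in lexicon and word not in vocab:
            vocab.append(word)
    return vocab


_PUNCT = (",", ".", ";", ":")
_NOTE_TYPES_CYCLE = ("admission", "weekly", "free", "hospice")


def _render_note(
    rng: np.random.Generator,
    mentions: list[str],
    vocab: list[str],
) -> str:
    """Compose one note: filler tokens with drug mentions inserted."""
    n_filler = int(rng.integers(20, 45))
    tokens = list(rng.choice(vocab, size=n_filler))
    for surface in mentions:
        pos = int(rng.integers(0, len(tokens) + 1))
        tokens.insert(pos, surface)
    out = []
    for tok in tokens:
        if rng.random() < 0.10:
            tok = tok.capitalize()
        if rng.random() < 0.15:
            tok = tok + str(rng.choice(_PUNCT))
        out.append(tok)
    return " ".join(out)


def simulate_cohort(
    cfg: SimulationConfig, lexicon: Optional[DrugLexicon] = None
) -> SyntheticCohort:
    """Generate a synthetic cohort from a config.

    The latent group is drawn per patient (fair coin); intervals come
    from group-specific log-normals placed symmetrically around the
    target median; drug sets are independent Bernoulli draws with
    group-specific probabilities, then co-prescription pairs are
    jointly boosted; notes embed each true drug at least once, using
    a brand synonym at the configured rate. Fully reproducible from
    ``cfg.seed``.
    """
    if lexicon is None:
        lexicon = load_default_lexicon()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    profiles = cfg.resolved_profiles()
    terms = [p.term for p in profiles]

    latent_early = rng.random(n) < 0.5

    # intervals: log-normal per latent group, mixture median on target
    log_m = math.log(cfg.median_interval_days)
    log_s = math.log(cfg.group_separation)
    mu = np.where(latent_early, log_m + log_s, log_m - log_s)
    intervals = np.rint(rng.lognormal(mean=mu, sigma=cfg.interval_dispersion)).astype(int)
    intervals = np.maximum(intervals, 0)

    # drug sets: independent Bernoulli, then joint pair boosts
    has_drug = np.zeros((n, len(terms)), dtype=bool)
    for j, prof in enumerate(profiles):
        p = np.where(latent_early, prof.p_early, prof.p_late)
        has_drug[:, j] = rng.random(n) < p
    col = {t: j for j, t in enumerate(terms)}
    for a, b, boost in cfg.coprescription_pairs:
        hit = rng.random(n) < boost
        has_drug[hit, col[a]] = True
        has_drug[hit, col[b]] = True

    vocab = _filler_vocab(cfg.filler_vocab_size, lexicon)
    base_death = dt.date(2017, 1, 1)

    patients: list[PatientRecord] = []
    notes: list[NoteDocument] = []
    truth_groups: dict[str, str] = {}
    truth_drugs: dict[str, list[str]] = {}
    width = len(str(n))

    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        death = base_death + dt.timedelta(days=int(rng.integers(0, 540)))
        referral = death - dt.timedelta(days=int(intervals[i]))
        sex = "male" if rng.random() < 0.605 else "female"
        age = int(np.clip(rng.normal(66, 15.8), 20, 100))
        patients.append(
            PatientRecord(pid, referral, death, {"sex": sex, "age": age})
        )
        truth_groups[pid] = "early" if latent_early[i] else "late"
        drugs = [terms[j] for j in range(len(terms)) if has_drug[i, j]]
        truth_drugs[pid] = drugs

        lo, hi = cfg.notes_per_patient
        n_notes = int(rng.integers(lo, hi + 1))
        # every true drug lands in at least one note; extras at random
        mentions_per_note: list[list[str]] = [[] for _ in range(n_notes)]
        for term in drugs:
            k = int(rng.integers(0, n_notes))
            mentions_per_note[k].append(term)
            if rng.random() < 0.3:  # occasional repeat mention
                mentions_per_note[int(rng.integers(0, n_notes))].append(term)
        span = max((death - referral).days, 1)
        for k in range(n_notes):
            surfaces = []
            for term in mentions_per_note[k]:
                synonyms = lexicon.synonyms(term)
                if synonyms and rng.random() < cfg.synonym_usage_rate:
                    surfaces.append(str(rng.choice(synonyms)))
                else:
                    surfaces.append(term)
            offset = int(rng.integers(0, span))
            notes.append(
                NoteDocument(
                    patient_id=pid,
                    text=_render_note(rng, surfaces, vocab),
                    note_type=_NOTE_TYPES_CYCLE[k % len(_NOTE_TYPES_CYCLE)],
                    date=(referral + dt.timedelta(days=offset)).isoformat(),
                )
            )

    truth = {
        "latent_group": truth_groups,
        "true_drugs": truth_drugs,
        "planted_pairs": [list(p[:2]) for p in cfg.coprescription_pairs],
        "profiles": {
            p.term: {"p_early": p.p_early, "p_late": p.p_late} for p in profiles
        },
        "seed": cfg.seed,
    }
    return SyntheticCohort(patients, notes, truth)


def write_cohort(cohort: SyntheticCohort, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write a synthetic cohort in the formats the pipeline consumes.

    Emits ``notes.jsonl``, ``cohort.csv`` and a ``truth.json``
    sidecar; output is byte-deterministic for a fixed cohort.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "notes": out_dir / "notes.jsonl",
        "cohort": out_dir / "cohort.csv",
        "truth": out_dir / "truth.json",
    }
    write_notes(cohort.notes, paths["notes"])
    write_cohort_csv(cohort.patients, paths["cohort"])
    paths["truth"].write_text(
        json.dumps(cohort.truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths
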