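"""Group-conditioned synthetic transcript generator.

Clinical interview corpora cannot be redistributed, so the pipeline is
exercised on synthetic transcripts that reproduce the *statistical
signatures* of psychotic speech at the graph level, with no linguistic
pretense: each transcript is a random walk over a growing lexicon.

At every step the walk either

* introduces a fresh lexeme (probability ``p_new``) — topic divergence;
* re-traverses an already-used outgoing transition from the current
  lexeme (probability ``p_retrace``, falling back to a fresh lexeme when
  the current lexeme has no traversed out-edges yet) — recurrence, the
  source of parallel edges and short loops;
* otherwise jumps to a uniformly chosen known lexeme — ordinary
  re-mention without edge repetition.

Topic-deviation spans open with per-element probability ``p_deviate``
and close geometrically with mean run length ``deviation_run``,
emulating the bursts in which a speaker abandons the anchor topic.
Report length is negative-binomial.  In synthetic mode one element is
one word (word_count = element count), so raw and word-normalized
measures differ only by report length.

The three default profiles encode the clinical signatures:
logorrheic, recurrent, topic-abandoning speech for the manic-like
profile (long reports, low ``p_new``, high ``p_retrace``/``p_deviate``);
short, non-recurrent, on-topic speech for the schizophrenic-like profile
(high ``p_new``, near-zero recurrence and deviation); and intermediate
parameters with strongly inflated between-subject dispersion for the
control-like profile.  Parameter values live in ``default_profiles``;
see docs/methods.md for the rationale behind each number.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .transcript import (
    Element,
    Group,
    Segment,
    SubjectRecord,
    Transcript,
    serialize_transcript,
)

__all__ = [
    "SyntheticProfile",
    "default_profiles",
    "generate_transcript",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class SyntheticProfile:
    """Parameters of the generative random walk for one group.

    mean_words / dispersion
        negative-binomial report length (elements = words in synthetic
        mode); smaller dispersion = heavier length tails.
    p_new, p_retrace, p_deviate, deviation_run
        walk probabilities described in the module docstring.
    subject_cv
        coefficient of variation of per-subject lognormal jitter applied
        to mean_words, p_new, p_retrace and p_deviate, modelling
        between-subject heterogeneity within a group.
    """

    name: str
    mean_words: float
    dispersion: float
    p_new: float
    p_retrace: float
    p_deviate: float
    deviation_run: float
    subject_cv: float = 0.0

    def __post_init__(self) -> None:
        for attr in ("p_new", "p_retrace", "p_deviate"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must be in [0, 1], got {v}")
        if self.p_new + self.p_retrace > 1.0:
            raise ValueError("p_new + p_retrace must not exceed 1")
        if self.mean_words < 2:
            raise ValueError("mean_words must be >= 2")
        if self.deviation_run < 1:
            raise ValueError("deviation_run must be >= 1")

    def sample_subject(self, rng: np.random.Generator) -> "SyntheticProfile":
        """Per-subject realization with lognormal parameter jitter.

        Probabilities are clipped so the profile invariants still hold;
        with subject_cv = 0 the profile is returned unchanged.
        """
        if self.subject_cv == 0.0:
            return self
        sigma = np.sqrt(np.log(1.0 + self.subject_cv**2))

        def jitter(value: float) -> float:
            return value * float(rng.lognormal(-(sigma**2) / 2.0, sigma))

        p_new = float(np.clip(jitter(self.p_new), 0.0, 1.0))
        p_retrace = float(np.clip(jitter(self.p_retrace), 0.0, 1.0 - p_new))
        return dataclasses.replace(
            self,
            mean_words=max(2.0, jitter(self.mean_words)),
            p_new=p_new,
            p_retrace=p_retrace,
            p_deviate=float(np.clip(jitter(self.p_deviate), 0.0, 1.0 - 1e-9)),
            subject_cv=0.0,
        )


def default_profiles() -> dict[str, SyntheticProfile]:
    """The three study-condition profiles, keyed by group label.

    Mean report lengths bracket the ~84 words/report scale of dream
    reports (cohort mean ~= 83), with manic-like reports substantially
    longer than schizophrenic-like ones.
    """
    return {
        "schizophrenic": SyntheticProfile(
            name="schizophrenic",
            mean_words=45,
            dispersion=15,
            p_new=0.75,
            p_retrace=0.02,
            p_deviate=0.01,
            deviation_run=2.0,
            subject_cv=0.08,
        ),
        "manic": SyntheticProfile(
            name="manic",
            mean_words=120,
            dispersion=15,
            p_new=0.30,
            p_retrace=0.38,
            p_deviate=0.08,
            deviation_run=4.0,
            subject_cv=0.08,
        ),
        "control": SyntheticProfile(
            name="control",
            mean_words=84,
            dispersion=6,
            p_new=0.50,
            p_retrace=0.15,
            p_deviate=0.03,
            deviation_run=3.0,
            subject_cv=0.35,
        ),
    }


def _draw_length(profile: SyntheticProfile, rng: np.random.Generator) -> int:
    """Negative-binomial element count, clamped to at least 2."""
    k, m = profile.dispersion, profile.mean_words
    n = rng.negative_binomial(k, k / (k + m))
    return max(2, int(n))


def generate_transcript(
    profile: SyntheticProfile,
    rng: np.random.Generator,
    subject_id: str = "synthetic",
    group: Group = Group.UNLABELED,
) -> Transcript:
    """Generate one transcript from a (per-subject) profile.

    Deterministic given the generator state.  With ``p_new = 1`` and
    ``p_deviate = 0`` the result is a pure chain: N = words,
    E = words - 1 and every recurrence measure is zero.
    """
    n_elements = _draw_length(profile, rng)
    lexicon: list[str] = []
    traversed: dict[str, list[str]] = {}  # node -> targets of traversed out-edges

    def fresh() -> str:
        w = f"w{len(lexicon):03d}"
        lexicon.append(w)
        traversed[w] = []
        return w

    elements: list[Element] = []
    in_deviation = False
    deviation_left = 0
    current = fresh()

    def segment_for_next() -> Segment:
        nonlocal in_deviation, deviation_left
        if in_deviation:
            deviation_left -= 1
            if deviation_left <= 0:
                in_deviation = False
            return Segment.DEVIATION
        if profile.p_deviate > 0 and rng.random() < profile.p_deviate:
            run = int(rng.geometric(1.0 / profile.deviation_run))
            if run > 1:
                in_deviation = True
                deviation_left = run - 1
            return Segment.DEVIATION
        return Segment.ANCHOR

    elements.append(
        Element(lexeme=current, segment=segment_for_next(), position=0)
    )
    for pos in range(1, n_elements):
        u = rng.random()
        if u < profile.p_new:
            nxt = fresh()
        elif u < profile.p_new + profile.p_retrace and traversed[current]:
            nxt = traversed[current][rng.integers(len(traversed[current]))]
        elif u < profile.p_new + profile.p_retrace:
            nxt = fresh()  # no traversed out-edge yet: fall back to a new lexeme
        else:
            nxt = lexicon[rng.integers(len(lexicon))]
        traversed[current].append(nxt)
        current = nxt
        elements.append(
            Element(lexeme=current, segment=segment_for_next(), position=pos)
        )

    return Transcript(
        subject_id=subject_id,
        group=group,
        elements=elements,
        word_count=len(elements),  # synthetic mode: one word per element
    )


def generate_cohort(
    profiles: Optional[dict[str, SyntheticProfile]] = None,
    n_per_group: int = 8,
    seed: int = 0,
) -> list[tuple[Transcript, SubjectRecord]]:
    """Generate ``n_per_group`` subjects per profile, deterministically.

    Subject ids are ``<group>_<index>``; group labels follow the profile
    keys.  The default study design is 8 subjects in each of the three
    groups (24 transcripts).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if profiles is None:
        profiles = default_profiles()
    rng = np.random.default_rng(seed)
    corpus: list[tuple[Transcript, SubjectRecord]] = []
    for group_name in profiles:
        profile = profiles[group_name]
        group = Group(group_name) if group_name in Group._value2member_map_ else Group.UNLABELED
        for i in range(n_per_group):
            subject_profile = profile.sample_subject(rng)
            sid = f"{group_name}_{i:02d}"
            t = generate_transcript(subject_profile, rng, subject_id=sid, group=group)
            corpus.append(
                (t, SubjectRecord(subject_id=sid, group=group, word_count=t.word_count))
            )
    return corpus


def write_cohort(
    corpus: list[tuple[Transcript, SubjectRecord]],
    outdir: str | Path,
    profiles: Optional[dict[str, SyntheticProfile]] = None,
    seed: Optional[int] = None,
) -> Path:
    """Write transcripts, metadata CSV and a manifest JSON to ``outdir``.

    The manifest records the profiles and seed so a cohort on disk is
    reproducible from the manifest alone.  Returns the metadata path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t, rec in corpus:
        (outdir / f"{t.subject_id}.txt").write_text(
            serialize_transcript(t) + "\n", encoding="utf-8"
        )
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group.value,
                "word_count": rec.word_count,
            }
        )
    meta_path = outdir / "metadata.csv"
    pd.DataFrame(rows).to_csv(meta_path, index=False)
    manifest = {
        "seed": seed,
        "n_subjects": len(corpus),
        "profiles": {
            name: dataclasses.asdict(p) for name, p in (profiles or {}).items()
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    return meta_path
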