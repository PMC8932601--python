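"""SAM and HAM-A anxiety labeling.

Two schemes, each at two granularities:

* SAM (per trial): four regions of the valence/arousal plane, applied with
  precedence Severe > Moderate > Light > Normal; scores outside every region
  are Unlabelled (excluded, not an error).
* HAM-A (per subject): four severity bins of the 0-56 total. Bin edges in the
  source overlap at the printed boundaries ("0 to 12", "12 to 20"); bins here
  are [0,12], (12,20], (20,25], (25,56] — first bin closed, later bins
  left-open — so every score maps to exactly one class.

The two-level scheme is the deterministic merge {Normal,Light} -> "Light
Anxiety", {Moderate,Severe} -> "Severe Anxiety", the only merge consistent
with the study's printed two- and four-level instance counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

FOUR_LEVEL = ("Normal", "Light", "Moderate", "Severe")
TWO_LEVEL = ("Light Anxiety", "Severe Anxiety")
UNLABELLED = "Unlabelled"

#: four-level class -> latent level index used by the generator
LEVEL_INDEX = {c: i for i, c in enumerate(FOUR_LEVEL)}


def label_sam_four(valence: float, arousal: float) -> str:
    """Four-level label from SAM valence/arousal, with rule precedence."""
    v, a = float(valence), float(arousal)
    if 0 <= v <= 2 and 7 <= a <= 9:
        return "Severe"
    if 2 < v <= 4 and 6 < a < 7:
        return "Moderate"
    if 4 < v <= 5 and 5 < a <= 6:
        return "Light"
    if v < 5 and a > 5:
        return "Normal"
    return UNLABELLED


def label_hama_four(ham_a: float) -> str:
    """Four-level label from a HAM-A total in [0, 56]."""
    h = float(ham_a)
    if not (0 <= h <= 56):
        raise ValueError(f"HAM-A score must lie in [0, 56], got {ham_a!r}")
    if h <= 12:
        return "Normal"
    if h <= 20:
        return "Light"
    if h <= 25:
        return "Moderate"
    return "Severe"


def merge_to_two_level(four_level: str) -> str:
    """Collapse four-level classes to the binary scheme."""
    if four_level in ("Normal", "Light"):
        return "Light Anxiety"
    if four_level in ("Moderate", "Severe"):
        return "Severe Anxiety"
    if four_level == UNLABELLED:
        return UNLABELLED
    raise ValueError(f"unknown four-level class {four_level!r}")


def label_trial(scores, scheme: str, granularity: int) -> str:
    """Label one trial's scores under a scheme ('SAM' or 'HAM-A') and
    granularity (2 or 4)."""
    if scheme == "SAM":
        lab = label_sam_four(scores.valence, scores.arousal)
    elif scheme == "HAM-A":
        lab = label_hama_four(scores.ham_a)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if granularity == 4:
        return lab
    if granularity == 2:
        return merge_to_two_level(lab)
    raise ValueError(f"granularity must be 2 or 4, got {granularity!r}")


@dataclass
class LabelSet:
    """Per-epoch labels under one scheme/granularity."""

    scheme: str
    granularity: int
    labels: list[str] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[str, int]:
        return dict(Counter(self.labels))

    @property
    def classes(self) -> tuple[str, ...]:
        ordered = FOUR_LEVEL if self.granularity == 4 else TWO_LEVEL
        return tuple(c for c in ordered if c in set(self.labels))


def expand_trial_labels(trial_labels, epochs_per_trial: int | None = None,
                        provenance: list[tuple[str, str, int]] | None = None,
                        scheme: str = "SAM", granularity: int = 4) -> LabelSet:
    """Broadcast per-trial labels to per-epoch labels.

    Either pass an ordered sequence of trial labels with a fixed
    ``epochs_per_trial``, or a mapping ``(subject_id, trial_id) -> label``
    together with the epoch matrix's ``provenance`` (which then defines the
    per-trial epoch counts). A trial present in the provenance but absent from
    the mapping is an error.
    """
    if provenance is not None:
        if not isinstance(trial_labels, dict):
            raise ValueError("provenance-based expansion requires a mapping "
                             "(subject_id, trial_id) -> label")
        labels = []
        for subj, trial, _ in provenance:
            key = (subj, trial)
            if key not in trial_labels:
                raise ValueError(f"no label for trial {key}")
            labels.append(trial_labels[key])
        return LabelSet(scheme=scheme, granularity=granularity, labels=labels)
    if epochs_per_trial is None or epochs_per_trial < 1:
        raise ValueError("epochs_per_trial must be >= 1")
    labels = [lab for lab in trial_labels for _ in range(epochs_per_trial)]
    return LabelSet(scheme=scheme, granularity=granularity, labels=labels)


def label_recordings(recordings, scheme: str, granularity: int) -> dict:
    """Map each recording's (subject_id, trial_id) to its trial label."""
    return {(r.subject_id, r.trial_id): label_trial(r.scores, scheme, granularity)
            for r in recordings}
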