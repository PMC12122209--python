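"""Class-selection fusion of two classifier outputs.

Two classifiers view the same sample: CP, the presence specialist (trained on
a local-detail view, trusted for the majority class P), and CA, the absence
specialist (global-context view, trusted for the minority class A). Writing
mu(P|CP) for CP's calibrated confidence in its P call and mu(A|CA) for CA's
confidence in its A call, the decision rules are:

  (a) CP = P and CA = P                          -> P   (consensus)
  (b) CP = A and CA = A                          -> A   (consensus)
  (c) CP = P, CA = A, mu(A|CA) > mu(P|CP)        -> A   (conflict: CA more confident)
  (d) CP = P, CA = A, mu(A|CA) < mu(P|CP)        -> P   (conflict: CP more confident)

Two situations the four rules leave open are handled by an explicit,
configurable policy rather than silently:

  * a score tie in the (c)/(d) conflict, mu(A|CA) == mu(P|CP): ``tie_rule``
    (default ``prefer_P`` — a missed dysplastic lesion is the costly error);
  * the reversed disagreement CP = A, CA = P, where each classifier votes
    *against* its own specialty: ``uncovered_rule`` (default
    ``confidence_vote``, extending the conflict principle of (c)/(d)
    symmetrically — the classifier more confident in its own call wins;
    ``prefer_specialist`` instead lets CP decide P-membership, yielding A).

The fused presence score for ROC analysis is, by default, the winning
classifier's calibrated mu(P) (``score_rule="selected_classifier"``);
``"average"`` uses the mean of the two mu(P) values instead.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .classifier import ClassifierOutput
from .data_io import Label

__all__ = ["FusionPolicy", "FusionDecision", "fuse", "write_decisions"]

_TIE_RULES = ("prefer_P", "prefer_A")
_UNCOVERED_RULES = ("confidence_vote", "prefer_specialist")
_SCORE_RULES = ("selected_classifier", "average")


@dataclass(frozen=True)
class FusionPolicy:
    tie_rule: str = "prefer_P"
    uncovered_rule: str = "confidence_vote"
    score_rule: str = "selected_classifier"

    def __post_init__(self) -> None:
        if self.tie_rule not in _TIE_RULES:
            raise ValueError(f"tie_rule must be one of {_TIE_RULES}")
        if self.uncovered_rule not in _UNCOVERED_RULES:
            raise ValueError(f"uncovered_rule must be one of {_UNCOVERED_RULES}")
        if self.score_rule not in _SCORE_RULES:
            raise ValueError(f"score_rule must be one of {_SCORE_RULES}")


@dataclass(frozen=True)
class FusionDecision:
    sample_id: str
    fused_label: Label
    fused_score_P: float
    rule_fired: str  # a | b | c | d | tie | uncovered


def fuse(
    out_CP: ClassifierOutput,
    out_CA: ClassifierOutput,
    policy: FusionPolicy = FusionPolicy(),
) -> list[FusionDecision]:
    """Apply the class-selection rules per sample.

    Exactly one rule fires for each sample. Both outputs must carry the same
    sample-id sequence.
    """
    if out_CP.sample_ids != out_CA.sample_ids:
        for i, (a, b) in enumerate(zip(out_CP.sample_ids, out_CA.sample_ids)):
            if a != b:
                raise ValueError(
                    f"sample id mismatch at position {i}: CP={a!r} vs CA={b!r}"
                )
        raise ValueError(
            f"sample id sequences differ in length: "
            f"{len(out_CP.sample_ids)} vs {len(out_CA.sample_ids)}"
        )

    decisions = []
    for i, sid in enumerate(out_CP.sample_ids):
        lp = out_CP.labels[i]
        la = out_CA.labels[i]
        mu_p_cp = float(out_CP.score_P[i])   # mu(P | CP)
        mu_a_ca = float(out_CA.score_A[i])   # mu(A | CA)
        cp_score_p = float(out_CP.score_P[i])
        ca_score_p = float(out_CA.score_P[i])

        if lp is Label.P and la is Label.P:
            rule, label, winner_score = "a", Label.P, cp_score_p
        elif lp is Label.A and la is Label.A:
            rule, label, winner_score = "b", Label.A, ca_score_p
        elif lp is Label.P and la is Label.A:
            if mu_a_ca > mu_p_cp:
                rule, label, winner_score = "c", Label.A, ca_score_p
            elif mu_a_ca < mu_p_cp:
                rule, label, winner_score = "d", Label.P, cp_score_p
            else:
                rule = "tie"
                if policy.tie_rule == "prefer_P":
                    label, winner_score = Label.P, cp_score_p
                else:
                    label, winner_score = Label.A, ca_score_p
        else:  # CP = A, CA = P: each classifier votes against its specialty
            rule = "uncovered"
            if policy.uncovered_rule == "prefer_specialist":
                label, winner_score = Label.A, cp_score_p
            else:  # confidence_vote
                conf_cp = float(out_CP.score_A[i])  # CP's confidence in its A call
                conf_ca = ca_score_p                # CA's confidence in its P call
                if conf_ca > conf_cp:
                    label, winner_score = Label.P, ca_score_p
                else:  # tie goes to CP, the P-membership specialist, voting A
                    label, winner_score = Label.A, cp_score_p

        if policy.score_rule == "average":
            score = 0.5 * (cp_score_p + ca_score_p)
        else:
            score = winner_score
        decisions.append(FusionDecision(sid, label, score, rule))
    return decisions


def write_decisions(decisions: list[FusionDecision], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "fused_label", "fused_score_P", "rule_fired"])
        for d in decisions:
            w.writerow([d.sample_id, d.fused_label.value,
                        format(d.fused_score_P, ".17g"), d.rule_fired])
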