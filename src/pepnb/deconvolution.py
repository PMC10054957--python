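"""Semi-supervised personalization of allele models from patient pools.

A patient's eluted immunopeptidome is an unlabeled mixture of peptides
presented by up to six HLA allotypes. Deconvolution proceeds by
pseudo-labeling: score every eluted peptide under each allotype's
public-data model, assign it to the top two allotypes, add the assigned
peptides to the public training data, and retrain each allele's model
(feature selection included) on the augmented set. One round is the
default; the loop can be iterated.

When an allotype has no public training data at all, a fallback claims
for it the eluted peptides that no modeled allotype scores confidently
(maximum log odds below a threshold, default 0 -- evidence does not
favor binding to any modeled allele), seeding a de-novo model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import features as ft
from .errors import DegenerateDataError
from .model import BackgroundModel, NBModel, fit


@dataclass(frozen=True)
class PatientProfile:
    """A patient's HLA typing plus their unlabeled eluted peptide pool."""

    patient_id: str
    allotypes: tuple[str, ...]
    eluted: tuple[str, ...]

    def __post_init__(self) -> None:
        # homozygous allotypes collapse to one entry, order preserved
        seen = dict.fromkeys(self.allotypes)
        object.__setattr__(self, "allotypes", tuple(seen))
        if not 1 <= len(self.allotypes) <= 6:
            raise ValueError("a patient carries 1 to 6 distinct HLA-I allotypes")
        object.__setattr__(self, "eluted", tuple(self.eluted))


@dataclass(frozen=True)
class Assignment:
    """One eluted peptide's ranked allotype scores and its top-k labels."""

    peptide: str
    ranked: tuple[tuple[str, float], ...]
    assigned: tuple[str, ...]


def classify_allele(
    models: Mapping[str, NBModel], peptide: str
) -> list[tuple[str, float]]:
    """Rank allotypes for one peptide by descending log odds.

    Ties keep the input order of ``models``; the ranking is invariant
    to the prior odds.
    """
    if not models:
        raise ValueError("no models to classify against")
    scored = [(allele, m.log_odds(peptide)) for allele, m in models.items()]
    order = np.argsort(-np.array([s for _, s in scored]), kind="stable")
    return [scored[k] for k in order]


def pseudo_label(
    models: Mapping[str, NBModel],
    profile: PatientProfile,
    top_k: int = 2,
) -> list[Assignment]:
    """Assign every eluted peptide its top-``top_k`` allotypes.

    Only the profile's allotypes that have a model participate;
    allotypes without models are handled by :func:`fallback_assign`.
    """
    if not profile.eluted:
        raise DegenerateDataError(f"patient {profile.patient_id} has an empty eluted pool")
    avail = {a: models[a] for a in profile.allotypes if a in models}
    if not avail:
        raise DegenerateDataError(
            f"no models available for any allotype of patient {profile.patient_id}"
        )
    alleles = list(avail)
    score_mat = np.column_stack(
        [avail[a].score_many(list(profile.eluted)) for a in alleles]
    )
    out = []
    for row, pep in enumerate(profile.eluted):
        order = np.argsort(-score_mat[row], kind="stable")
        ranked = tuple((alleles[k], float(score_mat[row, k])) for k in order)
        out.append(
            Assignment(peptide=pep, ranked=ranked,
                       assigned=tuple(a for a, _ in ranked[:top_k]))
        )
    return out


def augment_training(
    public: Mapping[str, Sequence[str]], assignments: Sequence[Assignment]
) -> dict[str, list[str]]:
    """Public training sets extended with the pseudo-labeled peptides.

    A peptide assigned to two allotypes is added to both alleles'
    training sets.
    """
    training = {a: list(peps) for a, peps in public.items()}
    for asg in assignments:
        for allele in asg.assigned:
            training.setdefault(allele, []).append(asg.peptide)
    return training


def augment_and_retrain(
    public: Mapping[str, Sequence[str]],
    assignments: Sequence[Assignment],
    background: BackgroundModel | None = None,
    smoothing: str = "laplace",
    alpha: float = 1.0,
    reselect_features: bool = True,
    feature_sets: Mapping[str, ft.FeatureSet] | None = None,
) -> dict[str, NBModel]:
    """Retrain per-allele models on public + pseudo-labeled peptides.

    Feature selection (pan-allelic on the augmented pool, then
    allele-specific) is re-run by default; pass ``reselect_features=
    False`` with ``feature_sets`` to reuse existing ones. Alleles whose
    augmented training set is empty are skipped.
    """
    training = augment_training(public, assignments)
    training = {a: p for a, p in training.items() if p}
    if not training:
        raise DegenerateDataError("no training peptides for any allele")
    if background is None:
        background = BackgroundModel.natural()
    models: dict[str, NBModel] = {}
    pan = ft.select_pan_features(training) if reselect_features else None
    for allele, peps in training.items():
        if reselect_features:
            fs = ft.build_feature_set(pan, ft.select_allele_features(peps, pan))
        else:
            if feature_sets is None or allele not in feature_sets:
                raise ValueError(f"no feature set supplied for allele {allele}")
            fs = feature_sets[allele]
        models[allele] = fit(
            peps, fs, background=background, smoothing=smoothing,
            alpha=alpha, allele=allele,
        )
    return models


def deconvolve(
    public: Mapping[str, Sequence[str]],
    profile: PatientProfile,
    background: BackgroundModel | None = None,
    top_k: int = 2,
    rounds: int = 1,
    smoothing: str = "laplace",
    alpha: float = 1.0,
) -> tuple[list[Assignment], dict[str, NBModel]]:
    """Full cycle: fit public models, pseudo-label, augment, retrain.

    Runs ``rounds`` assign-augment-retrain iterations (one by default)
    and returns the final assignments and personalized models.
    """
    if rounds < 1:
        raise ValueError("at least one round required")
    if background is None:
        background = BackgroundModel.natural()
    seed_public = {a: list(public[a]) for a in profile.allotypes if public.get(a)}
    if not seed_public:
        raise DegenerateDataError("no public data for any allotype of the patient")
    models = augment_and_retrain(
        seed_public, [], background=background, smoothing=smoothing, alpha=alpha
    )
    assignments: list[Assignment] = []
    for _ in range(rounds):
        assignments = pseudo_label(models, profile, top_k=top_k)
        models = augment_and_retrain(
            seed_public, assignments, background=background,
            smoothing=smoothing, alpha=alpha,
        )
    return assignments, models


def fallback_assign(
    profile: PatientProfile,
    models: Mapping[str, NBModel],
    orphan_allele: str,
    tau: float = 0.0,
) -> list[str]:
    """Eluted peptides not confidently claimed by any modeled allotype.

    A peptide belongs to the orphan allotype's seed set when its maximum
    log odds across all modeled allotypes is below ``tau`` (default 0:
    the evidence does not favor binding to any modeled allele).
    """
    if orphan_allele not in profile.allotypes:
        raise ValueError(f"{orphan_allele!r} is not an allotype of {profile.patient_id}")
    avail = {a: models[a] for a in profile.allotypes if a in models and a != orphan_allele}
    if not avail:
        raise DegenerateDataError("fallback needs at least one modeled allotype")
    if not profile.eluted:
        raise DegenerateDataError("empty eluted pool")
    score_mat = np.column_stack(
        [m.score_many(list(profile.eluted)) for m in avail.values()]
    )
    best = score_mat.max(axis=1)
    out = [pep for pep, s in zip(profile.eluted, best) if s < tau]
    if not out:
        warnings.warn(
            f"every eluted peptide is confidently claimed; no seed peptides for "
            f"{orphan_allele}", stacklevel=2,
        )
    return out
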