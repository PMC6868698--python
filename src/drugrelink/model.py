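"""Model/Results interface tying the pipeline stages together.

``DrugDiseaseModel`` holds a (training-view) association matrix together
with the raw side similarities and all stage configurations.  ``fit`` runs
the whole pipeline for a given set of labelled pairs:

1. sigmoid kernels of drug and disease interaction profiles;
2. logistic rescaling and ClusterONE cohesive-module boosting of the
   structure (drug) and semantic (disease) similarities;
3. per-pair kernel-vs-side fusion;
4. descriptor assembly and convolutional encoder training;
5. random-forest (or SVM) training on the encoded features.

The returned ``DrugDiseaseResults`` scores new pairs, ranks candidate drugs
for a disease and renders a summary.  Everything downstream of the
association matrix passed at construction is derived from that matrix
alone, so cross-validation can hand in a training view with held-out
positives zeroed and incur no information leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classify import ClassifierConfig, score_pairs, train_classifier
from .dataio import (
    AssociationMatrix,
    SimilarityMatrix,
    read_association_matrix,
    read_similarity_matrix,
)
from .features import ConvolutionalEncoder, EncoderConfig, build_descriptor_grids, grid_side
from .similarity import (
    KernelParams,
    LogisticParams,
    build_coassociation_graph,
    cluster_one,
    enhance_similarity,
    fuse_similarity,
    logistic_adjust,
    sigmoid_kernel,
)

logger = logging.getLogger(__name__)

__all__ = ["ClusterParams", "DrugDiseaseModel", "DrugDiseaseResults"]


@dataclass(frozen=True)
class ClusterParams:
    """ClusterONE parameters shared by the drug and disease graphs."""

    penalty_per_vertex: float = 2.0
    density_threshold: float = 0.0
    overlap_threshold: float = 0.8


class DrugDiseaseModel:
    """Drug-disease association model over one (training-view) matrix.

    Parameters
    ----------
    associations
        Binary diseases x drugs matrix; the training view (held-out
        positives already zeroed, if any).
    drug_similarity, disease_similarity
        Raw chemical-structure and semantic similarity matrices over the
        model's drugs and diseases.
    """

    def __init__(
        self,
        associations: AssociationMatrix,
        drug_similarity: SimilarityMatrix,
        disease_similarity: SimilarityMatrix,
        *,
        kernel_params: KernelParams = KernelParams(),
        logistic_params: LogisticParams = LogisticParams(),
        cluster_params: ClusterParams = ClusterParams(),
        encoder_config: EncoderConfig | None = None,
        classifier_config: ClassifierConfig = ClassifierConfig(),
        precomputed: tuple[SimilarityMatrix, SimilarityMatrix] | None = None,
    ):
        if drug_similarity.entity_ids != associations.drug_ids:
            raise ValueError("drug similarity identifiers do not match association columns")
        if disease_similarity.entity_ids != associations.disease_ids:
            raise ValueError("disease similarity identifiers do not match association rows")
        self.associations = associations
        self.drug_similarity = drug_similarity
        self.disease_similarity = disease_similarity
        self.kernel_params = kernel_params
        self.logistic_params = logistic_params
        self.cluster_params = cluster_params
        side = grid_side(associations.n_drugs, associations.n_diseases)
        self.encoder_config = (
            encoder_config if encoder_config is not None else EncoderConfig.for_grid(side)
        )
        self.classifier_config = classifier_config
        self._precomputed = precomputed

    @classmethod
    def from_files(cls, association_path, drug_similarity_path, disease_similarity_path, **kw):
        """Build a model from the canonical TSV layout."""
        return cls(
            read_association_matrix(association_path),
            read_similarity_matrix(drug_similarity_path),
            read_similarity_matrix(disease_similarity_path),
            **kw,
        )

    # -- similarity pipeline --------------------------------------------

    def _enhanced_side(self, raw: SimilarityMatrix, axis: str) -> SimilarityMatrix:
        adjusted = logistic_adjust(raw, self.logistic_params)
        graph = build_coassociation_graph(self.associations, axis)
        clusters = cluster_one(
            graph,
            penalty_per_vertex=self.cluster_params.penalty_per_vertex,
            density_threshold=self.cluster_params.density_threshold,
            overlap_threshold=self.cluster_params.overlap_threshold,
        )
        return enhance_similarity(adjusted, clusters)

    def fused_similarities(self) -> tuple[SimilarityMatrix, SimilarityMatrix]:
        """Fused drug and disease similarity matrices from the training view."""
        if self._precomputed is not None:
            return self._precomputed
        kr = sigmoid_kernel(self.associations, "drugs", self.kernel_params)
        ki = sigmoid_kernel(self.associations, "diseases", self.kernel_params)
        de = self._enhanced_side(self.drug_similarity, "drugs")
        ds = self._enhanced_side(self.disease_similarity, "diseases")
        rsim = fuse_similarity(kr, de, self.associations, "drugs")
        sim = fuse_similarity(ki, ds, self.associations, "diseases")
        self._precomputed = (rsim, sim)
        return self._precomputed

    # -- fitting ---------------------------------------------------------

    def fit(
        self, pairs: list[tuple[str, str]], labels, seed: int | None = None
    ) -> "DrugDiseaseResults":
        """Train encoder and classifier on labelled (drug_id, disease_id) pairs."""
        if seed is not None:
            self.encoder_config = self.encoder_config.with_seed(seed)
            self.classifier_config = self.classifier_config.with_seed(seed)
        rsim, sim = self.fused_similarities()
        grids = build_descriptor_grids(rsim, sim, pairs)
        y = np.asarray(labels, dtype=int)
        encoder = ConvolutionalEncoder(self.encoder_config, grids.shape[1]).fit(grids, y)
        features = encoder.encode(grids)
        classifier = train_classifier(features, y, self.classifier_config)
        train_scores = score_pairs(classifier, features)
        return DrugDiseaseResults(
            model=self,
            encoder=encoder,
            classifier=classifier,
            rsim=rsim,
            sim=sim,
            train_pairs=list(pairs),
            train_labels=y,
            train_scores=train_scores,
        )


@dataclass
class DrugDiseaseResults:
    """Fitted pipeline: fused similarities, trained encoder and classifier."""

    model: DrugDiseaseModel
    encoder: ConvolutionalEncoder
    classifier: object
    rsim: SimilarityMatrix
    sim: SimilarityMatrix
    train_pairs: list[tuple[str, str]]
    train_labels: np.ndarray
    train_scores: np.ndarray = field(repr=False, default=None)

    def score_pairs(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        """Association probability for each (drug_id, disease_id) pair."""
        grids = build_descriptor_grids(self.rsim, self.sim, pairs)
        return score_pairs(self.classifier, self.encoder.encode(grids))

    def predict(self, pairs: list[tuple[str, str]], threshold: float = 0.5) -> np.ndarray:
        """Hard 0/1 association calls at the given probability threshold."""
        return (self.score_pairs(pairs) >= threshold).astype(int)

    def rank_drugs(self, disease_id: str) -> list[tuple[str, str, float]]:
        """All drugs ranked by predicted association probability with one disease."""
        self.model.associations.disease_index(disease_id)  # raises on unknown id
        drugs = list(self.model.associations.drug_ids)
        scores = self.score_pairs([(d, disease_id) for d in drugs])
        order = sorted(range(len(drugs)), key=lambda k: (-scores[k], drugs[k]))
        return [(drugs[k], disease_id, float(scores[k])) for k in order]

    def summary(self) -> str:
        """Plain-text description of the fitted model."""
        am = self.model.associations
        y = self.train_labels
        acc = float(((self.train_scores >= 0.5).astype(int) == y).mean()) if len(y) else float("nan")
        lines = [
            "Drug-disease association model",
            "=" * 46,
            f"diseases: {am.n_diseases}    drugs: {am.n_drugs}",
            f"known associations (training view): {am.n_associations}",
            f"descriptor grid: {self.encoder.side} x {self.encoder.side}",
            f"encoder: conv {self.encoder.cfg.conv_kernel}x{self.encoder.cfg.conv_kernel}"
            f" x{self.encoder.cfg.n_filters} -> pool {self.encoder.cfg.pool}x{self.encoder.cfg.pool}"
            f" -> dense {self.encoder.cfg.dense_units}",
            f"classifier: {self.model.classifier_config.backend}",
            f"training pairs: {len(self.train_pairs)} "
            f"({int(y.sum())} positive / {int((1 - y).sum())} negative)",
            f"final encoder loss: {self.encoder.loss_history[-1]:.4f}"
            if self.encoder.loss_history else "final encoder loss: n/a",
            f"training accuracy at 0.5: {100 * acc:.2f}%",
        ]
        return "\n".join(lines)
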