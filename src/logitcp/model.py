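"""Model / Results interface over the variational inference core.

`BayesianLogisticCP` is constructed from an association tensor plus the two
similarity matrices; :meth:`BayesianLogisticCP.fit` runs the coordinate-ascent
variational algorithm and returns a :class:`BayesianLogisticCPResults` object
carrying the posterior summaries, the objective trace, the ARD spectrum, and
prediction / serialization helpers.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import inference
from .inference import ModelConfig, VariationalState
from .similarity import SimilarityMatrix
from .tensorops import AssociationTensor

__all__ = ["BayesianLogisticCP", "BayesianLogisticCPResults"]

_SCHEMA_VERSION = 1


class BayesianLogisticCP:
    """Kernel Bayesian logistic CP decomposition of a binary association tensor.

    Parameters
    ----------
    Y : AssociationTensor
        Binary miRNA × disease × type tensor.
    mirna_similarity, disease_similarity : SimilarityMatrix
        Kernel matrices S^m and S^d, aligned to Y's registries.
    rank : int
        Initial number of CP components; automatic rank determination shrinks
        surplus components, so this is an upper bound, capped at
        ``min(I*J, I*K, J*K)``.
    importance_weight : float
        Weight ``c >= 1`` on known positive triples in the likelihood.
    alpha, beta : float
        Gamma hyperparameters of the ARD precisions.

    Examples
    --------
    >>> from logitcp import synthetic
    >>> Y, Sm, Sd, truth = synthetic.generate(seed=0)
    >>> model = BayesianLogisticCP(Y, Sm, Sd, rank=8)
    >>> res = model.fit(seed=0)
    >>> res.effective_rank()[0] >= 1
    True
    """

    def __init__(
        self,
        Y: AssociationTensor,
        mirna_similarity: SimilarityMatrix,
        disease_similarity: SimilarityMatrix,
        rank: int = 20,
        importance_weight: float = 2.0,
        alpha: float = 1.0,
        beta: float = 1.0,
    ):
        self.Y = Y
        self.Sm = mirna_similarity.reindexed(Y.mirna_ids)
        self.Sd = disease_similarity.reindexed(Y.disease_ids)
        I, J, K = Y.shape
        self.rank = int(min(rank, I * J, I * K, J * K))
        self.importance_weight = float(importance_weight)
        self.alpha = float(alpha)
        self.beta = float(beta)

    @classmethod
    def from_dataframes(
        cls,
        triplets: pd.DataFrame,
        mirna_similarity: pd.DataFrame,
        disease_similarity: pd.DataFrame,
        **kwargs,
    ) -> "BayesianLogisticCP":
        """Build from a 3-column triple table and labeled similarity frames."""
        from .cli_io import tensor_from_frame, similarity_from_frame

        Y = tensor_from_frame(triplets)
        Sm = similarity_from_frame(mirna_similarity, Y.mirna_ids)
        Sd = similarity_from_frame(disease_similarity, Y.disease_ids)
        return cls(Y, Sm, Sd, **kwargs)

    def config(self, **overrides) -> ModelConfig:
        base = dict(
            R=self.rank,
            c=self.importance_weight,
            alpha=self.alpha,
            beta=self.beta,
        )
        base.update(overrides)
        return ModelConfig(**base)

    def fit(
        self,
        max_iter: int = 200,
        tol: float = 1e-5,
        seed: int = 0,
        jitter: float = 1e-10,
        callback=None,
    ) -> "BayesianLogisticCPResults":
        """Run mean-field variational inference and wrap the fitted state."""
        cfg = self.config(max_iter=max_iter, tol=tol, seed=seed, jitter=jitter)
        state = inference.fit(self.Y, self.Sm, self.Sd, cfg, callback=callback)
        return BayesianLogisticCPResults(self, cfg, state)


class BayesianLogisticCPResults:
    """Fitted posterior summaries, diagnostics and prediction."""

    def __init__(self, model: BayesianLogisticCP, config: ModelConfig, state: VariationalState):
        self.model = model
        self.config = config
        self.state = state

    # -- estimates ---------------------------------------------------------

    @property
    def factors(self):
        """Posterior means of the CP factors (G: miRNA, H: disease, W: type)."""
        return self.state.G.mean, self.state.H.mean, self.state.W.mean

    @property
    def lambda_means(self) -> np.ndarray:
        """Posterior means of the ARD precisions (the rank spectrum)."""
        return self.state.ard.lambda_tilde

    @property
    def objective_trace(self) -> list:
        return list(self.state.objective_trace)

    @property
    def n_iter(self) -> int:
        return self.state.iteration

    @property
    def converged(self) -> bool:
        return self.state.iteration < self.config.max_iter

    def effective_rank(self, threshold_ratio: float = 100.0):
        """(count, retained component indices) from the ARD spectrum."""
        return inference.effective_rank(self.state, threshold_ratio)

    # -- prediction --------------------------------------------------------

    def predict(self) -> np.ndarray:
        """Posterior-mean association probabilities, shape (I, J, K)."""
        return inference.predict(self.state)

    def predict_frame(self) -> pd.DataFrame:
        """All scored triples as a tidy frame sorted by descending score."""
        P = self.predict()
        Y = self.model.Y
        I, J, K = Y.shape
        idx = np.indices((I, J, K)).reshape(3, -1)
        df = pd.DataFrame(
            {
                "mirna": [Y.mirna_ids[i] for i in idx[0]],
                "disease": [Y.disease_ids[j] for j in idx[1]],
                "type": [Y.type_names[k] for k in idx[2]],
                "score": P.reshape(-1),
                "known": Y.values.reshape(-1).astype(int),
            }
        )
        return df.sort_values("score", ascending=False, kind="stable").reset_index(
            drop=True
        )

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary."""
        I, J, K = self.model.Y.shape
        count, retained = self.effective_rank()
        lam = self.lambda_means
        lines = [
            "Bayesian logistic CP decomposition (variational fit)",
            "=" * 56,
            f"tensor shape:        {I} miRNAs x {J} diseases x {K} types",
            f"known triples:       {self.model.Y.n_known} "
            f"(density {100 * self.model.Y.density:.3f}%)",
            f"initial rank R:      {self.config.R}",
            f"importance weight c: {self.config.c}",
            f"sweeps run:          {self.n_iter} "
            f"({'converged' if self.converged else 'max_iter reached'})",
            f"final objective:     {self.objective_trace[-1]:.4f}",
            f"effective rank:      {count}  (components {retained})",
            f"sigma_g / sigma_h:   {self.state.noise.sigma_g_mean:.4g} / "
            f"{self.state.noise.sigma_h_mean:.4g}",
            "",
            "ARD precision spectrum (lambda_r, ascending):",
        ]
        for r in np.argsort(lam):
            tag = "active" if int(r) in retained else "shrunk"
            lines.append(f"  component {int(r):>2d}: {lam[r]:>12.4f}  [{tag}]")
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------

    def save(self, path):
        """Serialize posterior summaries + config + trace to one .npz archive."""
        s = self.state
        meta = {
            "schema_version": _SCHEMA_VERSION,
            "config": {
                "R": self.config.R,
                "c": self.config.c,
                "alpha": self.config.alpha,
                "beta": self.config.beta,
                "max_iter": self.config.max_iter,
                "tol": self.config.tol,
                "seed": self.config.seed,
                "jitter": self.config.jitter,
            },
            "mirna_ids": self.model.Y.mirna_ids,
            "disease_ids": self.model.Y.disease_ids,
            "type_names": self.model.Y.type_names,
            "iteration": s.iteration,
        }
        np.savez_compressed(
            path,
            meta=json.dumps(meta),
            Y=self.model.Y.values,
            Sm=self.model.Sm.values,
            Sd=self.model.Sd.values,
            G_mean=s.G.mean, G_cov=s.G.row_cov,
            H_mean=s.H.mean, H_cov=s.H.row_cov,
            W_mean=s.W.mean, W_cov=s.W.row_cov,
            U_mean=s.U.mean, U_cov=s.U.col_cov,
            V_mean=s.V.mean, V_cov=s.V.col_cov,
            ard_alpha=s.ard.alpha_tilde, ard_beta=s.ard.beta_tilde,
            noise=np.array([s.noise.a_g, s.noise.b_g, s.noise.a_h, s.noise.b_h]),
            xi=s.xi,
            trace=np.asarray(s.objective_trace),
        )

    @classmethod
    def load(cls, path) -> "BayesianLogisticCPResults":
        from .inference import (
            ARDPosterior,
            CouplingPosterior,
            FactorPosterior,
            NoisePosterior,
        )

        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            if meta["schema_version"] != _SCHEMA_VERSION:
                raise ValueError(
                    f"unsupported archive schema {meta['schema_version']}"
                )
            Y = AssociationTensor(
                z["Y"], meta["mirna_ids"], meta["disease_ids"], meta["type_names"]
            )
            Sm = SimilarityMatrix(z["Sm"], meta["mirna_ids"])
            Sd = SimilarityMatrix(z["Sd"], meta["disease_ids"])
            cfgd = meta["config"]
            model = BayesianLogisticCP(
                Y, Sm, Sd,
                rank=cfgd["R"], importance_weight=cfgd["c"],
                alpha=cfgd["alpha"], beta=cfgd["beta"],
            )
            config = ModelConfig(**cfgd)
            noise = z["noise"]
            state = VariationalState(
                G=FactorPosterior(z["G_mean"], z["G_cov"]),
                H=FactorPosterior(z["H_mean"], z["H_cov"]),
                W=FactorPosterior(z["W_mean"], z["W_cov"]),
                U=CouplingPosterior(z["U_mean"], z["U_cov"]),
                V=CouplingPosterior(z["V_mean"], z["V_cov"]),
                ard=ARDPosterior(z["ard_alpha"], z["ard_beta"]),
                noise=NoisePosterior(*[float(x) for x in noise]),
                xi=z["xi"],
                objective_trace=[float(x) for x in z["trace"]],
                iteration=int(meta["iteration"]),
            )
        return cls(model, config, state)
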