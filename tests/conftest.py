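"""Shared fixtures: small hand-built matrices and the full injected-anomaly
replicate study used by the QC tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import genorep as g


def make_panel(n_snps: int, maf: float = 0.2) -> g.SnpPanel:
    """Tiny deterministic A/G panel for hand-built call matrices."""
    return g.SnpPanel(
        pd.DataFrame(
            {
                "snp_id": [f"snp{i}" for i in range(n_snps)],
                "chromosome": ["1"] * n_snps,
                "position": np.arange(1, n_snps + 1, dtype=np.int64) * 100,
                "allele_major": ["A"] * n_snps,
                "allele_minor": ["G"] * n_snps,
                "maf": [maf] * n_snps,
            }
        )
    )


def make_matrix(calls, sample_ids=None) -> g.GenotypeMatrix:
    calls = np.asarray(calls, dtype=np.int8)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(calls.shape[0])]
    return g.GenotypeMatrix(make_panel(calls.shape[1]), list(sample_ids), calls)


@pytest.fixture(scope="session")
def table1_study():
    """Full six-subject, four-replicate, five-experiment study at 20,000 SNPs
    with the anomaly pattern of interest injected: one heterozygosity-
    inflated replicate in E1 (subject F), one each for subjects B, C, E, F
    in E2, plus one low-call-rate replicate of subject B in E2.

    Returns (matrix, design, injected_het_samples, injected_lowcall_samples).
    """
    panel, truth = g.generate_truth(6, 20_000, 0.05, 0.5, seed=101)
    design = g.table1_design()
    model = g.ErrorModel(0.003, 0.005)
    calls = g.simulate_replicate_study(truth, design, model, seed=102)
    het_bad = ["F1_E1", "B1_E2", "C1_E2", "E1_E2", "F1_E2"]
    lowcall_bad = ["B2_E2"]
    for k, sid in enumerate(het_bad):
        calls = g.inject_low_quality(calls, sid, het_inflation=0.10, callrate_drop=0.0,
                                     seed=200 + k)
    for k, sid in enumerate(lowcall_bad):
        calls = g.inject_low_quality(calls, sid, het_inflation=0.0, callrate_drop=0.10,
                                     seed=300 + k)
    return calls, design, het_bad, lowcall_bad
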