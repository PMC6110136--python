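import pytest

from fepbench.records import DeltaDeltaG, PredictionRecord, Provenance


def make_record(
    tki="imatinib",
    mutation="T315I",
    exp=0.0,
    methods=None,
    censored=False,
    exp_sigma=0.0,
    replicates=None,
):
    """Convenience builder for a benchmark record with point predictions."""
    predictions = {
        name: DeltaDeltaG(value, sigma, False,
                          Provenance.PRIME if sigma == 0 else Provenance.FEP)
        for name, (value, sigma) in (methods or {}).items()
    }
    return PredictionRecord(
        tki=tki,
        mutation=mutation,
        experimental=DeltaDeltaG(exp, exp_sigma, censored, Provenance.EXPERIMENT),
        predictions=predictions,
        replicates=replicates,
    )


@pytest.fixture
def toy_records():
    """Six records with hand-assigned experimental and predicted ΔΔG values."""
    rows = [
        # (mutation, exp, pred)   cutoff at 10-fold is 1.3642
        ("T315I", 3.20, 2.80),   # resistant, predicted resistant
        ("E255K", 1.90, 1.00),   # resistant, predicted susceptible
        ("M244V", 0.30, 1.50),   # susceptible, predicted resistant
        ("G250E", 0.90, 0.70),   # susceptible, predicted susceptible
        ("Q252H", -0.40, -0.20),  # susceptible, predicted susceptible
        ("F317L", 1.20, 1.30),   # susceptible, predicted susceptible
    ]
    return [
        make_record(mutation=m, exp=e, methods={"fep": (p, 0.0)})
        for m, e, p in rows
    ]
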