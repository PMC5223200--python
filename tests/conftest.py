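import pytest

from glycolect.array_core import LectinAnnotation, Panel, SpotRecord, default_panel
from glycolect.simulate import GroupSpec, SimulationConfig


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture
def tiny_panel():
    return Panel(
        tuple(LectinAnnotation(n, s) for n, s in
              [("A", "Gal"), ("B", "GalNAc"), ("C", "Man")])
    )


def make_spot(lectin, fg, bg=0.0, *, slide_id="s1", block=1, row=1, column=1, flag=0):
    return SpotRecord(slide_id=slide_id, block=block, row=row, column=column,
                      lectin=lectin, fg_median=fg, bg_median=bg, flag=flag)


def block_of(net_by_lectin, *, slide_id="s1", block=1, bg=0.0, n_spots=3):
    """One block with every spot of a lectin at the same net intensity."""
    records = []
    for row, (lectin, net) in enumerate(net_by_lectin.items(), start=1):
        for col in range(1, n_spots + 1):
            records.append(make_spot(lectin, net + bg, bg, slide_id=slide_id,
                                     block=block, row=row, column=col))
    return records


def noise_free_config(panel, planted_fold=None, **overrides):
    defaults = dict(
        panel=panel,
        groups=(GroupSpec("M", "model"), GroupSpec("C", "control")),
        baseline_mu=5.0,
        planted_fold=planted_fold or {},
        spot_cv=0.0,
        block_sd=0.0,
        slide_sd=0.0,
        bg_level=100.0,
        bg_sd=0.0,
        dropout_rate=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
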