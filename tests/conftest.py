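import numpy as np
import pandas as pd
import pytest

from polarityscreen.morphometry import aggregate_cells_frame
from polarityscreen.screenstats import ScreenConfig, score_screens
from polarityscreen.synth import (
    EffectModel,
    generate_screen_set,
    layouts_to_frame,
    make_layouts,
)


@pytest.fixture(scope="session")
def default_screen():
    """Desk-scale triplicate screen with planted hits (2 plates, 50
    cells/well, paper-regime hit fractions), scored with defaults."""
    layouts = make_layouts(n_plates=2, n_screens=3)
    genes = sorted({t for lo in layouts for t in lo.library_wells().values()})
    effects = EffectModel.plant(genes, seed=11)
    cells, truth = generate_screen_set(layouts, effects, cells_per_well=50, seed=11)
    wells = aggregate_cells_frame(cells, layouts_to_frame(layouts), min_cells=20)
    config = ScreenConfig()
    ztable = score_screens(wells, config)
    return {
        "layouts": layouts,
        "genes": genes,
        "effects": effects,
        "cells": cells,
        "truth": truth,
        "wells": wells,
        "config": config,
        "ztable": ztable,
    }


@pytest.fixture(scope="session")
def null_screen():
    """All-null screen with independent replicates: 4 plates (344 genes),
    no planted effects, no gene-level between-screen noise."""
    layouts = make_layouts(n_plates=4, n_screens=3)
    genes = sorted({t for lo in layouts for t in lo.library_wells().values()})
    effects = EffectModel.plant(
        genes,
        seed=3,
        fraction_hits_decrease=0.0,
        fraction_hits_increase=0.0,
        between_screen_sd=0.0,
    )
    cells, truth = generate_screen_set(layouts, effects, cells_per_well=50, seed=3)
    wells = aggregate_cells_frame(cells, layouts_to_frame(layouts), min_cells=20)
    return {"wells": wells, "genes": genes, "truth": truth}


def rasterized_disk(radius: int, pad: int = 4) -> np.ndarray:
    from skimage.draw import disk

    size = 2 * radius + 2 * pad + 1
    img = np.zeros((size, size), dtype=bool)
    rr, cc = disk((size // 2, size // 2), radius)
    img[rr, cc] = True
    return img


@pytest.fixture(scope="session")
def disk_mask():
    return rasterized_disk(120)
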