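"""Shared fixtures: the expensive synthetic datasets are built once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from orfish.codebook import build_codebook
from orfish.moe_decode import decode_section, cells_to_frame
from orfish.synthetic import (
    SyntheticConfig,
    simulate_moe_cells,
    simulate_moe_section,
    simulate_ob_maps,
)


@pytest.fixture(scope="session")
def codebook50():
    return build_codebook([f"Olfr{i:04d}" for i in range(50)], seed=1)


@pytest.fixture(scope="session")
def moe_section(codebook50):
    """Default synthetic MOE section: 200 somas, 50 receptor types."""
    cfg = SyntheticConfig(seed=1)
    stack, truth = simulate_moe_section(cfg, codebook50, seed=1)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def decoded_section(codebook50, moe_section):
    """Cells decoded from the default section, with truth matching."""
    from scipy.spatial import cKDTree

    cfg, stack, truth = moe_section
    cells = decode_section(stack, codebook50)
    frame = cells_to_frame(cells)
    tree = cKDTree(truth.cells[["z", "y", "x"]].to_numpy())
    d, j = tree.query(frame[["z", "y", "x"]].to_numpy())
    matched = (d < cfg.soma_radius_um)
    correct = matched & (
        frame["receptor"].to_numpy() == truth.cells["receptor"].to_numpy()[j]
    )
    return {
        "cells": cells,
        "frame": frame,
        "truth": truth,
        "match_true_index": j,
        "matched": matched,
        "correct": correct,
        "config": cfg,
    }


@pytest.fixture(scope="session")
def atlas():
    """Atlas-scale synthetic MOE cells + OB maps with planted geometry."""
    from orfish.spatial_atlas import (
        basal_apical_index,
        central_peripheral_index,
        overlap_matrix,
    )

    cfg = SyntheticConfig(seed=3)
    cells, truth = simulate_moe_cells(cfg, n_sections=4, cells_per_or_per_section=20, seed=3)
    om = overlap_matrix(cells)
    cp, emb = central_peripheral_index(om, seed=0)
    ba = basal_apical_index(cells, cfg.epithelium_thickness_um)
    maps = simulate_ob_maps(truth, cfg, n_animals=2, seed=3)
    return {
        "config": cfg,
        "cells": cells,
        "truth": truth,
        "overlap": om,
        "cp": cp,
        "embedding": emb,
        "ba": ba,
        "maps": maps,
    }
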