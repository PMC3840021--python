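"""Parameter sweeps over synthetic corpora: how bits-per-base responds to
the maximum sequential model order and the minimum match length.

The order sweep uses sequential-only banks (the default orders filtered to
the ceiling under test) so the order effect is not masked by the sparse
models, which always look 16 bases back.  The default corpus carries
*approximate* repeats (copies point-mutated at 5%, fragmenting exact runs
below the match threshold): the first pass removes little, and the gain
from longer contexts shows in the second pass — the regime where model
order matters.  Timings are reported but never asserted anywhere — they
are hardware facts, not contracts.
"""

from __future__ import annotations

import time
from itertools import product

import pandas as pd

from .container import compress, report_bpb
from .fasta import SequenceRecord
from .models import DEFAULT_MASKS, DEFAULT_ORDERS
from .noref import MatchParams
from .synth import GenSpec, gen_repeats

__all__ = ["run_sweep"]


def run_sweep(
    param_grid: dict[str, list] | None = None,
    spec: GenSpec | None = None,
) -> pd.DataFrame:
    """Compress one synthetic corpus under a grid of parameters.

    ``param_grid`` maps ``"order"`` to maximum sequential orders and/or
    ``"L"`` to minimum match lengths; the cartesian product is evaluated.
    Returns a tidy table (order, L, bpb, n_tokens, time_s).
    """
    param_grid = param_grid or {"order": [2, 4, 8, 16], "L": [25]}
    spec = spec or GenSpec(length=200_000, seed=11, repeat_fraction=0.7,
                           repeat_len_mean=200.0, sub_rate=0.05)
    seq = gen_repeats(spec)
    rec = SequenceRecord("sweep", seq)
    orders_list = param_grid.get("order", [16])
    l_list = param_grid.get("L", [25])
    rows = []
    for order, L in product(orders_list, l_list):
        orders = tuple(o for o in DEFAULT_ORDERS if o <= order) or (order,)
        if order not in orders:
            orders = tuple(sorted(set(orders) | {order}))
        t0 = time.perf_counter()
        c = compress([rec], params=MatchParams(L=L), orders=orders, masks=())
        dt = time.perf_counter() - t0
        rows.append(
            {
                "order": order,
                "L": L,
                "bpb": report_bpb(c),
                "n_tokens": c.header["records"][0]["n_quads"],
                "time_s": dt,
            }
        )
    return pd.DataFrame(rows)
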