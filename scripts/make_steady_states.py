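"""Regenerate the shipped 1 Hz steady-state initial conditions.

Paces each cell variant from a crude resting guess for 3000 beats at 1 Hz and
freezes the final state vector into ``src/lqtsim/data/steady_state_*.json``.
Run from the repository root:

    python scripts/make_steady_states.py
"""

import json
import pathlib

from lqtsim.model import STATE_NAMES, ScalingFactors
from lqtsim.pacing import PacingProtocol, pace
from lqtsim.biomarkers import measure
from lqtsim.states import bootstrap_state

DATA = pathlib.Path(__file__).resolve().parents[1] / "src" / "lqtsim" / "data"


def main() -> None:
    for variant, stem in (("endocardial", "endo"), ("epicardial", "epi")):
        state = bootstrap_state()
        trace = None
        for _ in range(3):  # 3 x 1000 beats
            trace = pace(variant, ScalingFactors(),
                         PacingProtocol(n_beats=1000, record_last=2),
                         start_state=state)
            state = trace.final_state
        bm = measure(trace)
        payload = {
            "variant": variant,
            "pacing": {"cycle_length_ms": 1000.0, "pre_beats": 3000},
            "biomarkers": bm.as_dict(),
            "state": {name: float(val) for name, val in zip(STATE_NAMES, state)},
        }
        out = DATA / f"steady_state_{stem}.json"
        out.write_text(json.dumps(payload, indent=1) + "\n")
        print(f"{variant}: APD90={bm.apd90:.2f} ms -> {out}")


if __name__ == "__main__":
    main()
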