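"""Drop chips on the pegged chance board steered by extensor ratio.

ER positions the chip along the top of the board (flexion steers left,
extension right); the chip then takes a random path down eight peg rows.
The center slot, reachable reliably only via balanced co-activation, pays
the jackpot.
"""

import numpy as np

import myofeedback as mf

board = mf.BlinkoBoard()
rng = np.random.default_rng(3)
for er in (0.1, 0.5, 0.9):
    start = mf.blinko_start_slot(er, board)
    landings = [mf.blinko_drop(start, board, rng) for _ in range(2000)]
    mean_pts = np.mean([pts for _, pts in landings])
    print(f"ER={er:.1f}: start slot {start} "
          f"(${board.slot_values[start]}), mean payout ${mean_pts:.0f}")
counts = np.bincount([s for s, _ in landings], minlength=board.n_slots)
print("landing histogram from ER=0.9 start:", counts.tolist())
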