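"""Build the 30-minute passive-listening session and inspect its events.

The session alternates 16 trials of two conditions: a "long" 800-ms-IOI
stream with rare extra beats inserted at the midpoint (deviants, 15% of
gaps) and a "short" 400-ms-IOI stream with rare omissions (15% of slots).
Beats in the short condition that close a single-omission gap are the
adaptation-matched "standards": like every deviant, they are preceded by
audible intervals of exactly 800 then 400 ms, so the two key-event types
differ only in how expected they are.
"""

from oddbeat import build_session
from oddbeat.io import write_events_tsv

plan = build_session(n_pairs=8, total_min=30.0, p=0.15, seed=1)
events = plan.session_events()

print(f"trials: {len(plan.trials)}, total duration: {plan.total_duration:.0f} s")
print("event counts:", events["label"].value_counts().to_dict())

keys = events[events["label"].isin(["deviant", "standard_key"])]
print(f"key events: {len(keys)} "
      f"({(events['label'] == 'deviant').sum()} deviants, "
      f"{(events['label'] == 'standard_key').sum()} standards)")

write_events_tsv(events, "session_events.tsv")
print("wrote session_events.tsv")
# The deviant count lands near 165 per session: ~1100 eligible 800-ms gaps
# at a 15% insertion rate. Deviants and standards share the same local
# stimulus history, so any evoked-response difference reflects expectancy.
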