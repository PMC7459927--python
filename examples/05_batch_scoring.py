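"""Score a table of worker-task records in one pass.

Each record carries a worker's stature/body mass and a task's object
mass/height; the batch scorer reports RWL, comfort, lifting index, L5-S1
stresses and the risk category per row, flagging out-of-domain heights
instead of fabricating numbers for them.
"""

from waistload import TaskRecord, assess_batch, generate_fixture_tasks

records = [
    TaskRecord("standard-limit", 168, 59, 34.80, 70),
    TaskRecord("tall-light", 185, 90, 8.0, 55),
    TaskRecord("overload", 160, 55, 60.0, 50),
    TaskRecord("too-high", 168, 59, 5.0, 80),  # above the 74 cm hand height
]
for row in assess_batch(records):
    if row["in_domain"]:
        print(f"{row['worker_id']:>14s}: LI = {row['lifting_index_LI']:4.2f}"
              f"  C = {row['comfort_C']:+.3f}  N = {row['resultant_N']:7.1f} N"
              f"  -> {row['category']}")
    else:
        print(f"{row['worker_id']:>14s}: flagged ({row['flag'][:60]}...)")

# deterministic pseudo-random fixtures for stress-testing pipelines
tasks = generate_fixture_tasks(seed=42, n=5)
print(f"\n5 generated fixture tasks (seed 42): first = {tasks[0]}")
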