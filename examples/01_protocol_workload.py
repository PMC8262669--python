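"""Expected-workload accounting for the default 14-night home protocol.

The home period spans an arrival evening, 13 full four-session days and a
final two-session morning, with one sleep diary per night.
"""

from emafit import default_protocol, expected_questions, expected_tasks
from emafit.protocol import questions_per_full_day

proto = default_protocol("v2.0", home_nights=14)
ledger = expected_tasks(proto)

print(f"subjective-scale tasks : {ledger.subjective_scales}")
print(f"tapping-test tasks     : {ledger.fit_test}")
print(f"sleep diaries          : {ledger.sleep_diary}")
print(f"total tasks            : {ledger.total_tasks}")
print(f"total questions        : {expected_questions(proto)}")
print(f"questions per full day : {questions_per_full_day(proto)}")

# A fully adherent patient answers 55 x 11 scale questions plus 14 x 24 diary
# items = 941 questions, and performs 124 tasks, over the 14 nights at home.
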