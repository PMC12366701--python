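"""Attachment-site localization from MS/MS peak lists.

Runs the scorer on three noise-free exemplar spectra (alpha-tail extension,
alpha-tail branch at E445, beta-tail extension) and prints the ranked calls.
"""

from polyglu import localize, worked_example_fixtures

for name, ex in worked_example_fixtures().items():
    res = localize(ex["spectrum"], ex["candidates"])
    print(f"{name}:")
    print(f"  truth     : {ex['truth'].topology()}")
    print(f"  site call : {res.site_call}  (delta_score = {res.delta_score:.2f})")
    for form, score, matches in res.ranked:
        print(f"    {score:7.2f}  {form.topology():<12} ({len(matches)} ions matched)")
print()
print("delta_score is the margin between the best and second-best candidate;")
print("a call is only issued when it clears the threshold (default 1.0).")
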