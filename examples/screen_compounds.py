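"""ADME-screen the bundled four-herb candidate compound table.

Candidates must satisfy OB >= 30 %, Caco-2 > -0.4 and DL >= 0.18;
literature-whitelisted compounds bypass the screen and are kept with their
provenance flagged. The printed counts are the size of each partition.
"""

from netpharm import screen_compounds
from netpharm.datasets import load_candidate_compounds

records = load_candidate_compounds()
result = screen_compounds(records)

print(f"candidates : {len(records)}")
print(f"passed     : {len(result.passed)}   (meet all three ADME bounds)")
print(f"whitelisted: {len(result.whitelisted)}   (literature additions, screen bypassed)")
print(f"rejected   : {len(result.rejected)}")
print("\nfirst passed compounds:", ", ".join(r.name for r in result.passed[:5]))
print("whitelisted compounds  :", ", ".join(r.name for r in result.whitelisted[:5]), "...")
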