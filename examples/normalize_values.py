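"""Normalize individual temporal expressions to ISO 8601.

Builds a handful of classic clinical TE surfaces, normalizes each, and
prints the value.  Relative expressions need a reference time; here the
reference is an admission date, 2014-10-23.
"""

from tnorm import (
    TimexType,
    apply_offset,
    format_iso,
    normalize_direct,
    normalize_duration,
    normalize_set,
    parse_iso,
    parse_relative,
)

reference = parse_iso("2014-10-23")

print("direct (no reference needed):")
for surface in ["2014年6月3日", "2014年6月", "2014/10/11 7:48:16",
                "2014年6月3日上午7点20分4秒"]:
    print(f"  {surface}  ->  {format_iso(normalize_direct(surface, TimexType.DATE))}")

print("durations (approximation marker 余 drops):")
for surface in ["两年五个月", "1年余", "一个月"]:
    print(f"  {surface}  ->  {format_iso(normalize_duration(surface))}")

print(f"relative to {format_iso(reference)}:")
for surface in ["6天前", "1 周前", "72小时后", "目前"]:
    value = apply_offset(reference, parse_relative(surface))
    print(f"  {surface}  ->  {format_iso(value)}")

print("enumerated follow-up days (day 1 = the event day):")
value = normalize_set("第7、10、14天", parse_iso("2014-09-01"))
print(f"  第7、10、14天 after 2014-09-01  ->  {format_iso(value)}")

# 6天前 six days before the reference; 72小时后 is three whole days after;
# the day set counts the chemotherapy day itself as day one.
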