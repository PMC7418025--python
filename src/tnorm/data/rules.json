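{
  "comment": "Heuristic extraction rules. 'num' in a regex source is expanded to the shared numeral sub-pattern before compilation. Families: ABSOLUTE_DATE, CLOCK_TIME, RELATIVE, DURATION, SET, DEICTIC.",
  "numeral": "(?:\\d{1,3}|[一二两三四五六七八九十]{1,3})",
  "rules": [
    {"rule_id": "abs_cn_full", "family": "ABSOLUTE_DATE",
     "matcher": "\\d{4}年\\d{1,2}月\\d{1,2}日"},
    {"rule_id": "abs_cn_month", "family": "ABSOLUTE_DATE",
     "matcher": "\\d{4}年\\d{1,2}月(?!\\d)"},
    {"rule_id": "abs_cn_year", "family": "ABSOLUTE_DATE",
     "matcher": "\\d{4}年"},
    {"rule_id": "abs_dash", "family": "ABSOLUTE_DATE",
     "matcher": "\\d{4}-\\d{1,2}(?:-\\d{1,2})?"},
    {"rule_id": "abs_slash", "family": "ABSOLUTE_DATE",
     "matcher": "\\d{4}/\\d{1,2}/\\d{1,2}"},
    {"rule_id": "day_month_slash", "family": "ABSOLUTE_DATE",
     "matcher": "(?<![\\d/:])\\d{1,2}/\\d{1,2}(?![\\d/:])"},
    {"rule_id": "clock_colon", "family": "CLOCK_TIME",
     "matcher": "(?:\\d{4}[-/年]\\d{1,2}[-/月]\\d{1,2}日?[ \\t]?)?(?:上午|下午|凌晨|晚)?\\d{1,2}:\\d{2}(?::\\d{2})?"},
    {"rule_id": "clock_cn", "family": "CLOCK_TIME",
     "matcher": "(?:\\d{4}年\\d{1,2}月\\d{1,2}日[ \\t]?)?(?:上午|下午|凌晨|晚)?\\d{1,2}[点时]\\d{1,2}分(?:\\d{1,2}秒)?"},
    {"rule_id": "relative", "family": "RELATIVE",
     "matcher": "num[ \\t]?个?(?:小时|分钟|星期|年|月|周|天|日)[ \\t]?[余约多]?[前后]"},
    {"rule_id": "duration", "family": "DURATION",
     "matcher": "(?:num[ \\t]?个?(?:小时|分钟|星期|年|月|周|天|日|秒))+[余约多]?"},
    {"rule_id": "set_days", "family": "SET",
     "matcher": "第num(?:[、,，]num)*[天日]"},
    {"rule_id": "deictic", "family": "DEICTIC",
     "matcher": "目前|现在|入院时|出院时"}
  ]
}
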