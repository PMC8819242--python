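trial_id,stratum,source,reduction_pct
NovelSTART,low,observed,41
CAPTAIN,low,observed,20
QUEST,low,observed,-4
DREAM,low,observed,14
weighted_mean,low,observed,14
NovelSTART,low,predicted,0
CAPTAIN,low,predicted,0
QUEST,low,predicted,0
DREAM,low,predicted,0
weighted_mean,low,predicted,0
NovelSTART,high,observed,35
CAPTAIN,high,observed,35
QUEST,high,observed,62
DREAM,high,observed,52
weighted_mean,high,observed,41
NovelSTART,high,predicted,42
CAPTAIN,high,predicted,42
QUEST,high,predicted,42
DREAM,high,predicted,42
weighted_mean,high,predicted,42
NovelSTART,very_high,observed,81
CAPTAIN,very_high,observed,60
weighted_mean,very_high,observed,69
NovelSTART,very_high,predicted,72
CAPTAIN,very_high,predicted,72
QUEST,very_high,predicted,72
DREAM,very_high,predicted,72
weighted_mean,very_high,predicted,72
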