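trial_id,stratum,arm,n,rate,incidence,source
NovelSTART,low,control,18,0.05,,observed
NovelSTART,low,active,60,0.03,,observed
CAPTAIN,low,control,194,0.27,,observed
CAPTAIN,low,active,211,0.22,,observed
QUEST,low,control,106,0.56,,observed
QUEST,low,active,139,0.58,,observed
DREAM,low,control,23,1.98,,observed
DREAM,low,active,63,1.71,,observed
NovelSTART,high,control,201,0.05,,observed
NovelSTART,high,active,377,0.03,,observed
CAPTAIN,high,control,903,0.40,,observed
CAPTAIN,high,active,909,0.26,,observed
QUEST,high,control,514,1.07,,observed
QUEST,high,active,484,0.41,,observed
DREAM,high,control,145,2.46,,observed
DREAM,high,active,392,1.19,,observed
NovelSTART,very_high,control,51,0.13,,observed
NovelSTART,very_high,active,54,0.02,,observed
CAPTAIN,very_high,control,67,0.62,,observed
CAPTAIN,very_high,active,71,0.25,,observed
NovelSTART,low,control,18,0.07,,predicted
NovelSTART,low,active,60,0.07,,predicted
CAPTAIN,low,control,194,0.19,,predicted
CAPTAIN,low,active,211,0.19,,predicted
QUEST,low,control,106,0.53,,predicted
QUEST,low,active,139,0.53,,predicted
DREAM,low,control,23,0.74,,predicted
DREAM,low,active,63,0.74,,predicted
NovelSTART,high,control,201,0.13,,predicted
NovelSTART,high,active,377,0.07,,predicted
CAPTAIN,high,control,903,0.32,,predicted
CAPTAIN,high,active,909,0.19,,predicted
QUEST,high,control,514,0.93,,predicted
QUEST,high,active,484,0.53,,predicted
DREAM,high,control,145,1.28,,predicted
DREAM,high,active,392,0.74,,predicted
NovelSTART,very_high,control,51,0.26,,predicted
NovelSTART,very_high,active,54,0.07,,predicted
CAPTAIN,very_high,control,67,0.65,,predicted
CAPTAIN,very_high,active,71,0.19,,predicted
QUEST,very_high,control,,1.88,,predicted
QUEST,very_high,active,,0.82,,predicted
DREAM,very_high,control,,2.60,,predicted
DREAM,very_high,active,,1.14,,predicted
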