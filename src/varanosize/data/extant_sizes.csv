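genus,species,svl_mm,tl_mm,sex,comment
Lanthanotus,borneensis,400,,,max
Varanus,eremius,59,150,,approx
Varanus,brevicauda,70,136,,approx
Varanus,kingorum,98.4,326,,mean
Varanus,gilleni,113,235,,
Varanus,brevicauda,118,230,,
Varanus,caudolineatus,118,,F,
Varanus,primordius,120,,,approx
Varanus,caudolineatus,125,,M,
Varanus,storri,132,300,,approx
Varanus,eremius,160,400,,approx
Varanus,pilbarensis,169,,,max
Varanus,baritji,171,468,,mean
Varanus,glauerti,180,324,F,approx
Varanus,gilleni,186,,,
Varanus,glauerti,215,387,M,approx
Varanus,glebopalma,245,409.2,F,approx
Varanus,scalaris,250,600,,max
Varanus,semiremex,250,600,,
Varanus,griseus koniecznyi,255,620,,
Varanus,keithhornei,260,650,,
Varanus,kordensis,270,580,,max field
Varanus,glebopalma,290,484.3,M,approx
Varanus,dumerilii,292,900,,
Varanus,prasinus,295,845,,max
Varanus,tristis,305,800,,large
Varanus,macrei,313,912,F,
Varanus,flavescens,315,699,,
Varanus,exanthematicus,320,640,M,mean
Varanus,exanthematicus,320,640,F,mean
Varanus,mitchelli,320,,,max
Varanus,rudicollis,336,,,mean
Varanus,macrei,340,1000,M,
Varanus,griseus griseus,341,830,,
Varanus,marmoratus,342,,F,
Varanus,salvadorii,350,1160,,
Varanus,macrei,360,1110,M,
Varanus,salvadorii,360,1110,,
Varanus,gouldii,361,931,F,
Varanus,caerulivirensis,375,985,F,max
Varanus,marmoratus,391,,M,
Varanus,salvator,397,982,,
Varanus,caerulivirensis,400,1040,M,max
Varanus,melinus,420,1150,M,
Varanus,cumingi,431,1142,,mean
Varanus,griseus caspius,432,1050,,
Varanus,jobiensis,445,1195,M,
Varanus,jobiensis,450,1185,F,
Varanus,salvator,453,1198,,
Varanus,yemenensis,458,999,,
Varanus,bengalensis,460,1200,F,
Varanus,doreanus,460,1255,,voucher
Varanus,rosenbergi,470,,,max
Varanus,salvadorii,478,1486,,
Varanus,mertensi,480,1300,,max
Varanus,albigularis,500,1111,F,
Varanus,albigularis,500,1111,M,
Varanus,olivaceus,509,,F,
Varanus,niloticus,523,1308,F,
Varanus,mabitang,527,1268,F,type
Varanus,yuwonoi,532,1877,F,holotype
Varanus,spenceri,550,1250,,large
Varanus,bengalensis,580,1500,M,
Varanus,indicus,580,,,max
Varanus,gouldii,590,1410,M,
Varanus,rudicollis,590,1460,,max
Varanus,mabitang,640,1750,,
Varanus,niloticus,644,1610,M,
Varanus,giganteus,645,1494,,mean
Varanus,olivaceus,650,,M,
Varanus,giganteus,736,1690,M,
Varanus,panoptes,740,,,max
Varanus,salvadorii,745,2240,,
Varanus,ornatus,760,1900,,max
Varanus,varius,765,1920,,large
Varanus,komodoensis,775,1550,,Auffenberg approx
Varanus,komodoensis,840,1680,,Auffenberg approx
Varanus,komodoensis,850,1700,,mean
Varanus,salvadorii,850,2550,,
Varanus,salvadorii,863,2650,,
Varanus,giganteus,880,1940,,approx
Varanus,komodoensis,1540,3020,,max field
Varanus,beccarii,,950,,
Varanus,melinus,,950,F,
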