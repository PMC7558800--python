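compound_id,name,herbs,ob,caco2,dl,whitelist
C001,sitosterol,HQ|CX,67.77,1.1,0.59,false
C002,wallichilide,CX,65.76,1.35,0.38,false
C003,7-O-methylisomucronulatol,HQ,51.57,-0.11,0.77,false
C004,isoflavanone,HQ,56.02,0.54,0.8,false
C005,"1,7-dihydroxy-3,9-dimethoxy pterocarpene",HQ,69.58,-0.15,0.45,false
C006,"3,9-di-O-methylnissolin",HQ,39.41,0.52,0.8,false
C007,ergotamine,JC,46.83,0.7,0.62,false
C008,hederagenin,HQ,62.82,0.88,0.79,false
C009,isorhamnetin,HQ,31.15,0.75,0.33,false
C010,xanthinin,DL,39.5,0.56,0.5,false
C011,mairin,HQ,53.4,-0.19,0.28,false
C012,perlolyrine,CX,34.26,-0.31,0.6,false
C013,bassianin,JC,67.46,0.9,0.36,false
C014,"(6aR,11aR)-9,10-dimethoxy-6a,11a-dihydro-6H-benzofurano[3,2-c]chromen-3-ol",HQ,56.65,1.32,0.79,false
C015,bifendate,JC,68.77,0.66,0.76,false
C016,lupeol acetate,DL,38.62,-0.23,0.4,false
C017,calycosin,HQ,47.87,0.23,0.37,false
C018,kaempferol,HQ,58.55,0.58,0.69,false
C019,senkyunone,CX,37.67,0.45,0.36,false
C020,"(3S,8S,9S,10R,13R,14S,17R)-10,13-dimethyl-17-[(2R,5S)-5-propan-2-yloctan-2-yl]-2,3,4,7,8,9,11,12,14,15,16,17-dodecahydro-1H-cyclopenta[a]phenanthren-3-ol",DL,62.97,0.25,0.81,false
C021,hyrcanoside,DL,40.34,1.05,0.51,false
C022,mandenol,CX,58.47,0.76,0.73,false
C023,4-guanidino-1-butanol,DL,53.3,1.31,0.47,false
C024,cholesteryl ferulate,CX,33.22,0.41,0.37,false
C025,"(3R)-3-(2-hydroxy-3,4-dimethoxyphenyl)chroman-7-ol",HQ,74.64,0.21,0.44,false
C026,ecdysterone,DL,41.1,0.74,0.24,false
C027,quercetin,HQ|DL|JC,32.37,-0.26,0.84,false
C028,guanosine,JC,32.24,-0.05,0.38,false
C029,jaranol,HQ,54.57,1.19,0.82,false
C030,beauvericin,JC,73.86,-0.05,0.63,false
C031,myricanone,CX,71.71,0.6,0.32,false
C032,formononetin,HQ,47.25,0.38,0.29,false
C033,ligustrazine,CX,15.8,-0.53,0.12,true
C034,senkyunolide H,CX,21.43,-1.48,0.03,true
C035,ononin,HQ,22.74,-0.56,0.06,true
C036,calycosin 7-O-glucoside,HQ,6.98,-0.89,0.09,true
C037,butylphthalide,CX,13.99,-1.54,0.07,true
C038,senkyunolide I,CX,19.07,-0.78,0.12,true
C039,senkyunolide A,CX,3.52,-0.95,0.09,true
C040,coniferyl ferulate,CX,8.69,-1.4,0.02,true
C041,chlorogenic acid,CX,20.39,-0.74,0.13,true
C042,astragaloside IV,HQ,11.27,-0.96,0.06,true
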